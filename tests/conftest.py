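import pytest

from mirqtl.pipeline import run_pipeline
from mirqtl.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: seed 42, 20 true precursors, 5 decoys
    per violated-criterion class, 100 genes, 12 sRNA libraries."""
    return generate_dataset(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def pipeline_result(default_dataset):
    return run_pipeline(default_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced study for fast integration checks."""
    return generate_dataset(
        SyntheticConfig(
            seed=7,
            n_true_precursors=4,
            n_decoys_per_criterion=1,
            n_genes=30,
            chrom_length=30_000,
        )
    )
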