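"""Synthetic-data generator: determinism, composition, planted-truth
invariants and the abundance model."""

import numpy as np
import pytest

from mirqtl.synthetic import (
    SyntheticConfig,
    generate_dataset,
    generate_genome,
    generate_inventory,
    generate_promoter_alleles,
    simulate_tag_counts,
)
from mirqtl.util import revcomp

SMALL = dict(n_true_precursors=4, n_decoys_per_criterion=1, n_genes=30, chrom_length=30_000)


class TestGenome:
    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(seed=1, **SMALL)
        assert generate_genome(cfg) == generate_genome(cfg)

    def test_different_seeds_differ(self):
        a = generate_genome(SyntheticConfig(seed=1, **SMALL))
        b = generate_genome(SyntheticConfig(seed=2, **SMALL))
        assert a != b

    def test_gc_fraction_near_half(self):
        genome = generate_genome(SyntheticConfig(seed=3, **SMALL))
        seq = "".join(genome.values())
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.45 <= gc <= 0.55

    def test_uppercase_acgt_only(self):
        genome = generate_genome(SyntheticConfig(seed=4, **SMALL))
        assert set("".join(genome.values())) <= set("ACGT")

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(chrom_length=0, **{k: v for k, v in SMALL.items() if k != "chrom_length"})


class TestDatasetDeterminism:
    def test_datasets_byte_identical_under_seed(self, small_dataset):
        again = generate_dataset(small_dataset.config)
        assert again.genome == small_dataset.genome
        assert again.reads == small_dataset.reads
        assert all(
            again.degradome[lib].equals(small_dataset.degradome[lib])
            for lib in small_dataset.degradome
        )
        assert again.counts.equals(small_dataset.counts)


class TestPlantedTruth:
    def test_decoy_classes_planted_per_criterion(self, small_dataset):
        violated = sorted(d.violated_criterion for d in small_dataset.truth.decoys)
        assert violated == [1, 3, 5, 6, 7, 8]

    def test_true_precursor_count(self, small_dataset):
        assert len(small_dataset.truth.true_mirnas) == 4

    def test_every_true_mirna_has_a_target_pair(self, small_dataset):
        with_pairs = {p.mirna_name for p in small_dataset.truth.true_target_pairs}
        assert with_pairs == {m.name for m in small_dataset.truth.true_mirnas}

    def test_embedded_sites_are_reverse_complements(self, small_dataset):
        matures = {m.name: m.mature_sequence for m in small_dataset.truth.true_mirnas}
        for pair in small_dataset.truth.true_target_pairs:
            tx = small_dataset.transcripts[pair.gene_id + ".1"]
            site = tx[pair.site_offset : pair.site_offset + 21]
            assert site == revcomp(matures[pair.mirna_name])
            assert 1 <= pair.cleavage_position <= len(tx)

    def test_qtl_resident_genes_lie_inside_scaled_intervals(self, small_dataset):
        genes = small_dataset.genes.set_index("gene_id")
        intervals = {iv.chrom: iv for iv in small_dataset.truth.qtl_intervals}
        for gid in small_dataset.truth.qtl_resident_genes:
            g = genes.loc[gid]
            iv = intervals[g.chrom]
            assert iv.start <= g.start and g.end <= iv.end

    def test_qtl_gene_fraction(self, default_dataset):
        cfg = default_dataset.config
        expected = int(cfg.n_genes * cfg.qtl_fraction)
        assert len(default_dataset.truth.qtl_resident_genes) == expected


class TestReads:
    def test_every_read_carries_adapter_suffix_or_is_junk(self, small_dataset):
        adapter = small_dataset.config.adapter_sequence
        for lib, records in small_dataset.reads.items():
            hi_q = [seq for _, seq, qual in records if qual[0] == "I"]
            assert all(seq.endswith(adapter) for seq in hi_q)

    def test_criterion1_decoy_has_exactly_two_reads(self, small_dataset):
        decoy = next(
            d for d in small_dataset.truth.decoys if d.violated_criterion == 1
        )
        n = sum(
            seq.startswith(decoy.mature_sequence)
            for records in small_dataset.reads.values()
            for _, seq, _ in records
        )
        assert n == 2


class TestCounts:
    def test_planted_fold_change_in_expectation(self, default_dataset):
        """Averaged over libraries, drought/control ratio tracks 2^lfc."""
        truth, cfg = default_dataset.truth, default_dataset.config
        counts = simulate_tag_counts(truth, cfg, rng=np.random.default_rng(5))
        meta = cfg.library_meta
        ctrl = [m.library_id for m in meta if m.condition == "control"]
        drt = [m.library_id for m in meta if m.condition == "drought"]
        for mir in truth.true_mirnas:
            if abs(mir.planted_log2fc) < 0.1 or mir.base_mean < 50:
                continue
            ratio = counts.loc[mir.name, drt].mean() / max(
                counts.loc[mir.name, ctrl].mean(), 1
            )
            assert np.log2(ratio) == pytest.approx(mir.planted_log2fc, abs=0.8)


class TestInventory:
    IDS = [f"g{i}" for i in range(1746)]

    def test_fraction_zero_empty(self):
        assert generate_inventory(self.IDS, 0.0) == set()

    def test_fraction_one_is_everything(self):
        assert generate_inventory(self.IDS, 1.0) == set(self.IDS)

    def test_floor_of_fraction(self):
        assert len(generate_inventory(self.IDS, 0.28, seed=1)) == 488

    def test_deterministic(self):
        assert generate_inventory(self.IDS, 0.3, seed=5) == generate_inventory(
            self.IDS, 0.3, seed=5
        )


class TestPromoterAlleles:
    def test_motifs_planted_at_printed_positions(self):
        a, b, truth = generate_promoter_alleles(seed=3)
        assert a[1156 : 1156 + 12] == "TAACAAACTCCA"
        assert a[1144 : 1144 + 7] == "TCTGTTG"

    def test_exactly_two_substitutions_outside_motifs(self):
        a, b, truth = generate_promoter_alleles(seed=3)
        diffs = [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]
        assert diffs == truth["snp_positions"] and len(diffs) == 2
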