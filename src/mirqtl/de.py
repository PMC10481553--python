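"""Differential expression of miRNA counts between control and drought.

The selection contract follows the printed filters: a miRNA is eligible
when its raw count is at least 5 in both the control and the drought
libraries of a genotype, and differentially expressed when |log2FC| > 1
(strict) — optionally also requiring an FDR cutoff. The negative-binomial
shrinkage machinery of the original DESeq2 analysis is intentionally NOT
re-implemented; the significance stand-in is a two-sided exact binomial
test of the pooled drought count against the proportion expected from the
normalized library totals, with Benjamini-Hochberg adjustment."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_COUNT = 5
DEFAULT_LFC_THRESHOLD = 1.0
DEFAULT_ALPHA = 0.05
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class LibraryMeta:
    library_id: str
    genotype: str
    condition: str  # "control" | "drought"
    replicate: int


class CountMatrix:
    """miRNA x library raw counts with (genotype, condition, replicate) metadata."""

    def __init__(self, counts: pd.DataFrame, meta: list[LibraryMeta]):
        by_id = {m.library_id: m for m in meta}
        missing = [c for c in counts.columns if c not in by_id]
        if missing:
            raise ValueError(f"libraries without metadata: {missing}")
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        self.counts = counts.astype(int)
        self.meta = [by_id[c] for c in counts.columns]

    def libraries(self, genotype: str | None = None, condition: str | None = None) -> list[str]:
        return [
            m.library_id
            for m in self.meta
            if (genotype is None or m.genotype == genotype)
            and (condition is None or m.condition == condition)
        ]

    @property
    def genotypes(self) -> list[str]:
        seen: list[str] = []
        for m in self.meta:
            if m.genotype not in seen:
                seen.append(m.genotype)
        return seen


def count_filter(
    matrix: CountMatrix, genotype: str, min_count: int = DEFAULT_MIN_COUNT
) -> pd.Index:
    """miRNAs with summed raw count >= min_count in BOTH conditions."""
    ctrl = matrix.libraries(genotype, "control")
    drt = matrix.libraries(genotype, "drought")
    if not ctrl or not drt:
        raise ValueError(f"genotype {genotype}: both conditions must be present")
    c = matrix.counts[ctrl].sum(axis=1)
    d = matrix.counts[drt].sum(axis=1)
    return matrix.counts.index[(c >= min_count) & (d >= min_count)]


def normalize(counts: pd.DataFrame, method: str = "cpm") -> tuple[pd.DataFrame, pd.Series]:
    """Library-size normalization; returns (normalized matrix, size factors).

    "cpm": counts per million of the column total. "median-ratio": columns
    scaled by the median ratio to the row-wise geometric mean, computed on
    rows expressed in every library.
    """
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("all-zero library column")
    if method == "cpm":
        factors = totals / 1e6
    elif method == "median-ratio":
        positive = counts[(counts > 0).all(axis=1)]
        if not len(positive):
            raise ValueError("no row expressed in all libraries")
        log_geomean = np.log(positive).mean(axis=1)
        factors = pd.Series(
            {
                lib: float(np.exp(np.median(np.log(positive[lib]) - log_geomean)))
                for lib in counts.columns
            }
        )
    else:
        raise ValueError(f"unknown normalization method: {method}")
    return counts / factors, factors


def log2_fold_change(
    mean_drought: float, mean_control: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2((drought + pc) / (control + pc)); pseudocount guards zeros."""
    if mean_drought < 0 or mean_control < 0:
        raise ValueError("negative mean")
    return math.log2((mean_drought + pseudocount) / (mean_control + pseudocount))


def de_test(
    count_drought: int, count_control: int, total_drought: float, total_control: float
) -> float:
    """Two-sided exact binomial test of the drought share of pooled counts.

    Under the null of equal relative abundance the drought count is
    binomial in the pooled count with success probability
    total_drought / (total_drought + total_control).
    """
    if total_drought <= 0 or total_control <= 0:
        raise ValueError("library totals must be positive")
    n = count_drought + count_control
    if n == 0:
        return 1.0
    p0 = total_drought / (total_drought + total_control)
    return float(stats.binomtest(count_drought, n, p0, alternative="two-sided").pvalue)


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    matrix: CountMatrix,
    genotype: str,
    min_count: int = DEFAULT_MIN_COUNT,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    alpha: float | None = DEFAULT_ALPHA,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-miRNA DE table for one genotype.

    Replicates are pooled by summing before testing. Columns: normalized
    condition means, log2fc, p, fdr, passes_count_filter, is_de,
    direction. With alpha=None the call is fold-change-driven only, which
    matches selection by the printed filters.
    """
    ctrl = matrix.libraries(genotype, "control")
    drt = matrix.libraries(genotype, "drought")
    if not ctrl or not drt:
        raise ValueError(f"genotype {genotype}: both conditions must be present")
    counts = matrix.counts
    eligible = set(count_filter(matrix, genotype, min_count))
    ctrl_pool = counts[ctrl].sum(axis=1)
    drt_pool = counts[drt].sum(axis=1)
    pooled = pd.DataFrame({"control": ctrl_pool, "drought": drt_pool})
    # median-of-ratios is robust to composition shifts from strongly
    # regulated miRNAs, which would bias total-count scaling
    try:
        normed, factors = normalize(pooled, "median-ratio")
    except ValueError:
        normed, factors = normalize(pooled, "cpm")
    mean_c = normed["control"]
    mean_d = normed["drought"]
    total_c = float(factors["control"])
    total_d = float(factors["drought"])
    rows = []
    for mirna in counts.index:
        lfc = log2_fold_change(mean_d[mirna], mean_c[mirna], pseudocount)
        p = de_test(int(drt_pool[mirna]), int(ctrl_pool[mirna]), total_d, total_c)
        rows.append(
            {
                "mirna": mirna,
                "mean_control": float(mean_c[mirna]),
                "mean_drought": float(mean_d[mirna]),
                "log2fc": lfc,
                "p_value": p,
                "passes_count_filter": mirna in eligible,
            }
        )
    table = pd.DataFrame(rows).set_index("mirna")
    table["fdr"] = adjust_fdr(table["p_value"].to_numpy())
    sig = table["fdr"] <= alpha if alpha is not None else True
    table["is_de"] = (
        table["passes_count_filter"] & (table["log2fc"].abs() > lfc_threshold) & sig
    )
    table["direction"] = np.where(
        ~table["is_de"], "", np.where(table["log2fc"] > 0, "up", "down")
    )
    return table


def call_de(table: pd.DataFrame) -> pd.Index:
    """Index of miRNAs called differentially expressed in a DE table."""
    return table.index[table["is_de"]]
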