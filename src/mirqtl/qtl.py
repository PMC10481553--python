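"""QTL co-localization and evidence integration.

Intersects validated miRNA target genes with the three major rice 'yield
under drought' QTL intervals (qDTY1.1, qDTY3.1, qDTY12.1, defined verbatim
by their flanking microsatellite marker positions), flags support from a
drought-responsive gene inventory, builds the per-gene evidence table and
the multi-tool consensus regions, exports the miRNA-mRNA network, and
offers the locus-characterization scans (promoter motifs, allele
variants)."""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .util import normalize_seq, revcomp, round_half_up

# Printed marker intervals, 1-based inclusive bp. The chromosome is implied
# by the qDTY nomenclature (qDTY1.1 -> chromosome 1, etc.).
@dataclass(frozen=True)
class QTLInterval:
    name: str
    chrom: str
    start: int
    end: int
    flanking_markers: tuple[str, str]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


DEFAULT_QTL_INTERVALS = (
    QTLInterval("qDTY1.1", "Chr1", 33_053_493, 42_415_653, ("RM212", "RM12233")),
    QTLInterval("qDTY3.1", "Chr3", 30_912_691, 31_248_603, ("RM520", "RM416")),
    QTLInterval("qDTY12.1", "Chr12", 14_106_460, 17_395_485, ("RM28048", "RM512")),
)


def genes_in_interval(
    genes: pd.DataFrame, interval: QTLInterval, mode: str = "any-overlap"
) -> pd.DataFrame:
    """Genes intersecting (default) or fully contained in a QTL interval.

    `genes` needs gene_id/chrom/start/end columns with 1-based inclusive
    spans. An interval on a chromosome absent from the table returns an
    empty frame. Output is ordered by coordinate.
    """
    if mode not in ("any-overlap", "contained"):
        raise ValueError(f"unknown overlap mode: {mode}")
    on_chrom = genes[genes["chrom"] == interval.chrom]
    if mode == "any-overlap":
        hit = (on_chrom["start"] <= interval.end) & (on_chrom["end"] >= interval.start)
    else:
        hit = (on_chrom["start"] >= interval.start) & (on_chrom["end"] <= interval.end)
    return on_chrom[hit].sort_values(["start", "end", "gene_id"]).reset_index(drop=True)


def assign_qtl_membership(
    genes: pd.DataFrame,
    intervals: Sequence[QTLInterval] = DEFAULT_QTL_INTERVALS,
    mode: str = "any-overlap",
) -> pd.Series:
    """Per-gene QTL name (first matching interval) or None."""
    member = pd.Series([None] * len(genes), index=genes["gene_id"], dtype=object)
    for iv in intervals:
        for gid in genes_in_interval(genes, iv, mode)["gene_id"]:
            if member.loc[gid] is None:
                member.loc[gid] = iv.name
    return member


def percent(numerator: float, denominator: float, decimals: int = 0) -> float:
    """100*n/d rounded half-up, as reported percentages print."""
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    return round_half_up(100.0 * numerator / denominator, decimals)


def consensus(tool_sets: Mapping[str, set]) -> dict[frozenset, set]:
    """All Venn regions of the per-tool target-gene sets.

    Returns a map from the frozenset of tool names to the genes exclusive
    to exactly that combination; regions partition the union, so counts
    satisfy the inclusion-exclusion identities by construction.
    """
    names = sorted(tool_sets)
    regions: dict[frozenset, set] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(tool_sets[n]) for n in combo))
            outside = set().union(*(set(tool_sets[n]) for n in names if n not in combo)) if len(combo) < len(names) else set()
            regions[frozenset(combo)] = inside - outside
    return regions


def build_evidence_table(
    predictions: Mapping[str, Iterable[tuple[str, str]]],
    degradome_support: Mapping[tuple[str, str], tuple[int, int]] | None = None,
    inventory: Iterable[str] = (),
    genes: pd.DataFrame | None = None,
    intervals: Sequence[QTLInterval] = DEFAULT_QTL_INTERVALS,
    mode: str = "any-overlap",
) -> pd.DataFrame:
    """Per-gene evidence rows: predicting stages, degradome support,
    inventory membership, QTL residency and targeting miRNAs.

    `predictions` maps a stage/tool tag to (miRNA, gene) pairs;
    `degradome_support` maps (miRNA, gene) to (best category, n libraries).
    """
    degradome_support = degradome_support or {}
    inv = set(inventory)
    stage_by_gene: dict[str, set[str]] = {}
    mirnas_by_gene: dict[str, set[str]] = {}
    for stage, pairs in predictions.items():
        for mirna, gene in pairs:
            stage_by_gene.setdefault(gene, set()).add(stage)
            mirnas_by_gene.setdefault(gene, set()).add(mirna)
    rows = []
    for gene in sorted(stage_by_gene):
        support = [
            degradome_support[(m, gene)]
            for m in mirnas_by_gene[gene]
            if (m, gene) in degradome_support
        ]
        best_cat = min((c for c, _ in support), default=None)
        n_libs = max((n for _, n in support), default=0)
        rows.append(
            {
                "gene_id": gene,
                "predicted_by": ",".join(sorted(stage_by_gene[gene])),
                "mirnas": ",".join(sorted(mirnas_by_gene[gene])),
                "best_category": best_cat,
                "n_degradome_libraries": n_libs,
                "inventory_support": gene in inv,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "predicted_by", "mirnas", "best_category",
            "n_degradome_libraries", "inventory_support",
        ],
    )
    if genes is not None and len(table):
        membership = assign_qtl_membership(genes, intervals, mode)
        table["qtl"] = [
            membership.get(g, None) if g in membership.index else None
            for g in table["gene_id"]
        ]
    else:
        table["qtl"] = None
    return table


def inventory_support(
    table: pd.DataFrame, inventory: Iterable[str]
) -> tuple[pd.DataFrame, dict]:
    """Flag inventory membership and summarize support per stage.

    Summary holds (n_supported, n_total, percent) overall and for each
    predicting stage, with percents at 2 decimals.
    """
    inv = set(inventory)
    out = table.copy()
    out["inventory_support"] = out["gene_id"].isin(inv)
    n_total = len(out)
    n_sup = int(out["inventory_support"].sum())
    summary = {
        "overall": (n_sup, n_total, percent(n_sup, n_total, 2) if n_total else 0.0)
    }
    stages = sorted(
        {s for tags in out["predicted_by"] for s in str(tags).split(",") if s}
    )
    for stage in stages:
        sub = out[out["predicted_by"].str.split(",").apply(lambda t: stage in t)]
        k, n = int(sub["inventory_support"].sum()), len(sub)
        summary[stage] = (k, n, percent(k, n, 2) if n else 0.0)
    return out, summary


def export_network(table: pd.DataFrame, sif_path=None, tsv_path=None) -> pd.DataFrame:
    """miRNA->gene edge list (one edge per targeting miRNA) with evidence
    attributes, written in SIF and/or TSV dialects when paths are given."""
    if not len(table):
        raise ValueError("empty evidence table")
    edges = []
    for row in table.itertuples(index=False):
        for mirna in str(row.mirnas).split(","):
            if not mirna:
                continue
            edges.append(
                {
                    "mirna": mirna,
                    "gene_id": row.gene_id,
                    "best_category": row.best_category,
                    "qtl": row.qtl,
                    "inventory_support": row.inventory_support,
                }
            )
    edge_df = pd.DataFrame(edges).sort_values(["mirna", "gene_id"]).reset_index(drop=True)
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for e in edge_df.itertuples(index=False):
                fh.write(f"{e.mirna}\ttargets\t{e.gene_id}\n")
    if tsv_path is not None:
        edge_df.to_csv(tsv_path, sep="\t", index=False)
    return edge_df


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]",
    "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def scan_motifs(
    sequence: str, motifs: Iterable[str], strand: str = "+"
) -> list[tuple[str, int, str]]:
    """All (motif, 1-based position, strand) occurrences; overlaps allowed.

    Motifs may use IUPAC ambiguity codes. Scanning the minus strand reports
    positions of the match on the given sequence's coordinates.
    """
    seq = normalize_seq(sequence)
    target = seq if strand == "+" else revcomp(seq)
    hits = []
    for motif in motifs:
        pat = "".join(IUPAC[ch] for ch in normalize_seq(motif))
        for m in re.finditer(f"(?=({pat}))", target):
            pos = m.start() + 1
            if strand == "-":
                pos = len(seq) - (m.start() + len(m.group(1))) + 1
            hits.append((motif, pos, strand))
    return sorted(hits, key=lambda h: (h[0], h[1]))


def pairwise_variants(
    allele_a: str, allele_b: str
) -> list[tuple[int, str, str]]:
    """Variants between two allele sequences by global alignment.

    Needleman-Wunsch with match +1, mismatch -1, linear gap -2; positions
    are 1-based on allele A. Indels report '-' on the gapped side (an
    insertion in B is anchored at the preceding A position).
    """
    if not allele_a or not allele_b:
        raise ValueError("both allele sequences must be non-empty")
    a, b = normalize_seq(allele_a), normalize_seq(allele_b)
    aligner = Align.PairwiseAligner(
        mode="global", match_score=1, mismatch_score=-1,
        open_gap_score=-2, extend_gap_score=-2,
    )
    aln = aligner.align(a, b)[0]
    variants: list[tuple[int, str, str]] = []
    pos_a = 0
    for col_a, col_b in zip(aln[0], aln[1]):
        if col_a != "-":
            pos_a += 1
        if col_a == col_b:
            continue
        variants.append((max(pos_a, 1), col_a, col_b))
    return variants
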