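"""End-to-end orchestration: preprocess -> discover -> DE -> targets ->
degradome validation -> QTL/inventory integration.

`run_pipeline` consumes a SyntheticDataset (or equivalently the file-based
inputs read back into the same structures) and returns a PipelineResult
holding every intermediate product plus recovery metrics against the
planted truth when available."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import de as de_mod
from .de import CountMatrix
from .discovery import (
    CriteriaThresholds,
    MiRNACall,
    PrecursorCandidate,
    discover_mirnas,
)
from .preprocess import (
    MappedLocus,
    RawRead,
    SmallRNATag,
    collapse_tags,
    map_tags,
    preprocess_library,
)
from .qtl import build_evidence_table, consensus, export_network, inventory_support, percent
from .synthetic import SyntheticDataset
from .targets import (
    DegradomeHit,
    DegradomeProfile,
    TargetSite,
    build_profile,
    categorize_site,
    filter_hits,
    find_target_sites,
)


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    tags: list[SmallRNATag]
    loci: list[MappedLocus]
    calls: list[MiRNACall]
    candidates: list[PrecursorCandidate]
    count_matrix: CountMatrix | None
    de_tables: dict[str, pd.DataFrame]
    de_mirnas: set[str]
    target_sites: dict[str, list[TargetSite]]
    degradome_hits: list[DegradomeHit]
    site_categories: dict[TargetSite, dict[str, int | None]]
    evidence: pd.DataFrame
    network: pd.DataFrame | None
    summary: dict
    recovery: dict = field(default_factory=dict)


def _reads_from_records(records: list[tuple[str, str, str]]) -> list[RawRead]:
    return [
        RawRead(rid, seq, [ord(c) - 33 for c in qual]) for rid, seq, qual in records
    ]


def _gene_of(transcript_id: str) -> str:
    return transcript_id.rsplit(".", 1)[0]


def run_pipeline(
    dataset: SyntheticDataset,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    score_max: float = 3.0,
    kept_categories=(0, 1, 2),
    min_libraries: int = 1,
    de_alpha: float | None = 0.05,
    target_mirnas: str = "all",  # "all" passing calls or "de" only
) -> PipelineResult:
    cfg = dataset.config
    # --- preprocessing ----------------------------------------------------
    clean = {
        lib: preprocess_library(_reads_from_records(recs), cfg.adapter_sequence)
        for lib, recs in sorted(dataset.reads.items())
    }
    tags = collapse_tags(clean)
    loci = map_tags(tags, dataset.genome)
    # --- precursor discovery ---------------------------------------------
    calls, candidates = discover_mirnas(
        loci, dataset.genome, dataset.reference_matures, thresholds
    )
    unique_calls: dict[str, MiRNACall] = {}
    for call in calls:
        unique_calls.setdefault(call.mature_sequence, call)
    # --- differential expression ------------------------------------------
    lib_ids = [m.library_id for m in dataset.library_meta]
    rows = {
        call.name: [call.precursor.locus.tag.counts.get(lib, 0) for lib in lib_ids]
        for call in unique_calls.values()
    }
    de_tables: dict[str, pd.DataFrame] = {}
    de_set: set[str] = set()
    matrix = None
    if rows:
        matrix = CountMatrix(
            pd.DataFrame.from_dict(rows, orient="index", columns=lib_ids),
            dataset.library_meta,
        )
        for genotype in matrix.genotypes:
            table = de_mod.run_de(matrix, genotype, alpha=de_alpha)
            de_tables[genotype] = table
            de_set |= set(de_mod.call_de(table))
    # --- target prediction -------------------------------------------------
    selected = [
        c for c in unique_calls.values() if target_mirnas == "all" or c.name in de_set
    ]
    sites_default: list[TargetSite] = []
    sites_nogap: list[TargetSite] = []
    for call in selected:
        for tid in sorted(dataset.transcripts):
            seq = dataset.transcripts[tid]
            if len(seq) < len(call.mature_sequence):
                continue
            for site in find_target_sites(
                call.mature_sequence, seq, score_max,
                allow_gaps=True, mirna_id=call.name, transcript_id=tid,
            ):
                sites_default.append(site.tagged("scan_default"))
                if site.alignment.gap is None:
                    sites_nogap.append(site.tagged("scan_nogap"))
    # --- degradome validation ----------------------------------------------
    profiles: dict[str, dict[str, DegradomeProfile]] = {}
    for lib, df in dataset.degradome.items():
        profiles[lib] = {
            tid: build_profile(
                list(zip(sub["position"], sub["count"])), tid, lib
            )
            for tid, sub in df.groupby("transcript_id")
        }
    site_categories: dict[TargetSite, dict[str, int | None]] = {}
    for site in sites_default:
        per_lib: dict[str, int | None] = {}
        for lib in sorted(profiles):
            prof = profiles[lib].get(site.transcript_id)
            per_lib[lib] = (
                categorize_site(prof, site.cleavage_position) if prof else None
            )
        site_categories[site] = per_lib
    hits = filter_hits(site_categories, kept_categories, min_libraries)
    # --- integration --------------------------------------------------------
    predictions = {
        "scan_default": [(s.mirna_id, _gene_of(s.transcript_id)) for s in sites_default],
        "scan_nogap": [(s.mirna_id, _gene_of(s.transcript_id)) for s in sites_nogap],
        "degradome": [
            (h.site.mirna_id, _gene_of(h.site.transcript_id)) for h in hits
        ],
    }
    degradome_support = {
        (h.site.mirna_id, _gene_of(h.site.transcript_id)): (
            min(cat for _, cat in h.categories if cat is not None),
            h.n_supporting_libraries,
        )
        for h in hits
    }
    evidence = build_evidence_table(
        predictions,
        degradome_support,
        dataset.truth.inventory_genes,
        dataset.genes,
        dataset.truth.qtl_intervals,
    )
    evidence, inv_summary = inventory_support(evidence, dataset.truth.inventory_genes)
    network = export_network(evidence) if len(evidence) else None
    regions = consensus({k: {g for _, g in v} for k, v in predictions.items()})
    n_total = len(evidence)
    n_qtl = int(evidence["qtl"].notna().sum()) if n_total else 0
    summary = {
        "n_tags": len(tags),
        "n_calls": len(unique_calls),
        "n_de": len(de_set),
        "n_target_genes": n_total,
        "n_validated_genes": len({_gene_of(h.site.transcript_id) for h in hits}),
        "n_qtl_genes": n_qtl,
        "pct_qtl_genes": percent(n_qtl, n_total, 2) if n_total else 0.0,
        "inventory": inv_summary,
        "venn_regions": {
            "|".join(sorted(k)): len(v) for k, v in regions.items()
        },
    }
    result = PipelineResult(
        dataset, tags, loci, calls, candidates, matrix, de_tables, de_set,
        {"scan_default": sites_default, "scan_nogap": sites_nogap},
        hits, site_categories, evidence, network, summary,
    )
    result.recovery = compute_recovery(result)
    return result


def compute_recovery(result: PipelineResult) -> dict:
    """Score the pipeline against the planted ground truth."""
    truth = result.dataset.truth
    by_locus: dict[tuple, PrecursorCandidate] = {}
    for cand in result.candidates:
        if cand.locus is not None:
            by_locus[(cand.locus.chrom, cand.locus.strand, cand.locus.start, cand.locus.end)] = cand

    recalled = 0
    for mir in truth.true_mirnas:
        cand = by_locus.get((mir.chrom, "+", mir.mature_start, mir.mature_end))
        if cand is not None and cand.passed:
            recalled += 1
    decoys_exact = 0
    decoy_detail = []
    for decoy in truth.decoys:
        cand = by_locus.get((decoy.chrom, "+", decoy.mature_start, decoy.mature_end))
        fails = (
            [k for k, v in cand.criteria.items() if not v] if cand is not None else []
        )
        exact = fails == [decoy.violated_criterion]
        decoys_exact += exact
        decoy_detail.append((decoy.name, tuple(fails), exact))

    # planted (miRNA, gene, cleavage) triples validated at category 0
    name_of_mature = {m.mature_sequence: m.name for m in truth.true_mirnas}
    called_name = {}
    for call in result.calls:
        planted = name_of_mature.get(call.mature_sequence)
        if planted:  # first call per mature mirrors the pipeline's dedup
            called_name.setdefault(planted, call.name)
    cat0_by_site = {}
    for site, per_lib in result.site_categories.items():
        cats = [c for c in per_lib.values() if c is not None]
        if cats:
            cat0_by_site[(site.mirna_id, _gene_of(site.transcript_id), site.cleavage_position)] = min(cats)
    pairs_found = 0
    for pair in truth.true_target_pairs:
        called = called_name.get(pair.mirna_name)
        if called is None:
            continue
        best = cat0_by_site.get((called, pair.gene_id, pair.cleavage_position))
        if best == 0:
            pairs_found += 1
    planted_keys = {
        (called_name.get(p.mirna_name), p.gene_id, p.cleavage_position)
        for p in truth.true_target_pairs
    }
    false_cat0 = sum(
        1 for key, cat in cat0_by_site.items() if cat == 0 and key not in planted_keys
    )
    validated_qtl = {
        _gene_of(h.site.transcript_id)
        for h in result.degradome_hits
        if _gene_of(h.site.transcript_id) in truth.qtl_resident_genes
    }
    planted_qtl = truth.qtl_resident_genes & {
        p.gene_id for p in truth.true_target_pairs
    }
    return {
        "n_true": len(truth.true_mirnas),
        "n_recalled": recalled,
        "recall_pct": percent(recalled, len(truth.true_mirnas), 2)
        if truth.true_mirnas
        else 0.0,
        "n_decoys": len(truth.decoys),
        "n_decoys_exact": decoys_exact,
        "decoy_exact_pct": percent(decoys_exact, len(truth.decoys), 2)
        if truth.decoys
        else 0.0,
        "decoy_detail": decoy_detail,
        "n_planted_pairs": len(truth.true_target_pairs),
        "n_pairs_recovered_cat0": pairs_found,
        "n_false_category0": false_cat0,
        "qtl_validated_equals_planted": validated_qtl == planted_qtl,
        "n_qtl_validated": len(validated_qtl),
    }
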