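"""QTL co-localization, consensus regions, reported-percentage arithmetic,
network export and the locus-characterization scans."""

import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirqtl.qtl import (
    DEFAULT_QTL_INTERVALS,
    QTLInterval,
    build_evidence_table,
    consensus,
    export_network,
    genes_in_interval,
    inventory_support,
    pairwise_variants,
    percent,
    scan_motifs,
)
from mirqtl.synthetic import generate_promoter_alleles

QDTY = {iv.name: iv for iv in DEFAULT_QTL_INTERVALS}


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


class TestGenesInInterval:
    def test_printed_interval_bounds_stored_verbatim(self):
        assert (QDTY["qDTY1.1"].start, QDTY["qDTY1.1"].end) == (33_053_493, 42_415_653)
        assert (QDTY["qDTY3.1"].start, QDTY["qDTY3.1"].end) == (30_912_691, 31_248_603)
        assert (QDTY["qDTY12.1"].start, QDTY["qDTY12.1"].end) == (14_106_460, 17_395_485)
        assert QDTY["qDTY1.1"].flanking_markers == ("RM212", "RM12233")

    def test_gene_inside_qdty1(self):
        genes = _genes([("g", "Chr1", 34_000_000, 34_002_000, "+")])
        assert len(genes_in_interval(genes, QDTY["qDTY1.1"])) == 1

    def test_gene_far_outside(self):
        genes = _genes([("g", "Chr1", 10_000, 12_000, "+")])
        assert len(genes_in_interval(genes, QDTY["qDTY1.1"])) == 0

    def test_boundary_gene_overlap_vs_containment(self):
        genes = _genes([("g", "Chr3", 30_912_000, 30_913_000, "+")])
        assert len(genes_in_interval(genes, QDTY["qDTY3.1"], "any-overlap")) == 1
        assert len(genes_in_interval(genes, QDTY["qDTY3.1"], "contained")) == 0

    def test_single_bp_touch_is_inclusive(self):
        iv = QDTY["qDTY12.1"]
        touching = _genes(
            [("a", "Chr12", iv.end, iv.end + 500, "+"), ("b", "Chr12", iv.start - 500, iv.start, "+")]
        )
        assert len(genes_in_interval(touching, iv, "any-overlap")) == 2

    def test_unknown_chromosome_empty(self):
        genes = _genes([("g", "Chr7", 1, 100, "+")])
        assert genes_in_interval(genes, QDTY["qDTY1.1"]).empty

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            genes_in_interval(_genes([]), QDTY["qDTY1.1"], "nearby")

    def test_agrees_with_brute_force_scan(self):
        rng = random.Random(21)
        rows = []
        for i in range(300):
            chrom = rng.choice(["Chr1", "Chr3", "Chr12"])
            start = rng.randrange(1, 45_000_000)
            rows.append((f"g{i}", chrom, start, start + rng.randrange(200, 20_000), "+"))
        genes = _genes(rows)
        for iv in DEFAULT_QTL_INTERVALS:
            for mode in ("any-overlap", "contained"):
                got = set(genes_in_interval(genes, iv, mode)["gene_id"])
                expected = set()
                for gid, chrom, s, e, _ in rows:
                    if chrom != iv.chrom:
                        continue
                    hit = (
                        s <= iv.end and e >= iv.start
                        if mode == "any-overlap"
                        else s >= iv.start and e <= iv.end
                    )
                    if hit:
                        expected.add(gid)
                assert got == expected


class TestConsensus:
    def test_common_region(self):
        regions = consensus({"A": {"a", "b"}, "B": {"b", "c"}, "C": {"b"}})
        assert regions[frozenset(["A", "B", "C"])] == {"b"}
        assert regions[frozenset(["A"])] == {"a"}

    def test_disjoint_sets_have_empty_pairwise_regions(self):
        regions = consensus({"A": {"a"}, "B": {"b"}, "C": {"c"}})
        assert all(not v for k, v in regions.items() if len(k) > 1)

    def test_regions_partition_the_union(self):
        sets = {"A": {1, 2, 3, 4}, "B": {3, 4, 5}, "C": {4, 5, 6, 7}}
        regions = consensus(sets)
        union = set().union(*sets.values())
        assert sum(len(v) for v in regions.values()) == len(union)
        assert set().union(*regions.values()) == union


class TestPercent:
    @pytest.mark.parametrize(
        "n,d,k,expected",
        [
            (489, 1746, 0, 28),
            (91, 180, 2, 50.56),
            (235, 851, 2, 27.61),
            (347, 1364, 2, 25.44),
            (19, 61, 2, 31.15),
            (230, 489, 0, 47),
            (0, 10, 2, 0.0),
        ],
    )
    def test_reported_ratios(self, n, d, k, expected):
        assert percent(n, d, k) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent(1, 0)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 500), st.integers(1, 500), st.integers(0, 3))
    def test_complement_sums_to_hundred(self, a, b, k):
        a = min(a, b)
        total = percent(a, b, k) + percent(b - a, b, k)
        assert abs(total - 100.0) <= 10 ** (-k) + 1e-9


class TestEvidenceAndNetwork:
    def _table(self):
        preds = {
            "scan": [("mir1", "g1"), ("mir1", "g2"), ("mir1", "g3"), ("mir2", "g2")]
        }
        genes = _genes(
            [
                ("g1", "Chr1", 34_000_000, 34_001_000, "+"),
                ("g2", "Chr2", 1000, 2000, "+"),
                ("g3", "Chr12", 15_000_000, 15_001_000, "+"),
            ]
        )
        return build_evidence_table(preds, None, {"g2"}, genes)

    def test_rows_and_qtl_membership(self):
        table = self._table().set_index("gene_id")
        assert table.loc["g1", "qtl"] == "qDTY1.1"
        assert table.loc["g3", "qtl"] == "qDTY12.1"
        assert table.loc["g2", "qtl"] is None
        assert bool(table.loc["g2", "inventory_support"])

    def test_inventory_summary_percent(self):
        flagged, summary = inventory_support(self._table(), {"g2"})
        n, total, pct = summary["overall"]
        assert (n, total) == (1, 3) and pct == 33.33

    def test_network_edges_and_degree(self):
        edges = export_network(self._table())
        assert len(edges) == 4
        assert (edges["gene_id"] == "g2").sum() == 2  # targeted by two miRNAs

    def test_network_tsv_round_trip(self, tmp_path):
        path = tmp_path / "net.tsv"
        edges = export_network(self._table(), tsv_path=path)
        back = pd.read_csv(path, sep="\t")
        assert set(zip(back["mirna"], back["gene_id"])) == set(
            zip(edges["mirna"], edges["gene_id"])
        )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            export_network(pd.DataFrame())


class TestMotifScan:
    def test_planted_promoter_motifs_at_printed_positions(self):
        promoter, _, _ = generate_promoter_alleles(seed=5)
        hits = scan_motifs(promoter, ["TAACAAACTCCA", "TCTGTTG"])
        assert ("TAACAAACTCCA", 1157, "+") in hits
        assert ("TCTGTTG", 1145, "+") in hits

    def test_absent_motif_empty(self):
        assert scan_motifs("ACGTACGT", ["TTTTTT"]) == []

    def test_overlapping_occurrences_reported(self):
        assert [(m, p) for m, p, _ in scan_motifs("AAAA", ["AAA"])] == [
            ("AAA", 1),
            ("AAA", 2),
        ]

    def test_iupac_codes_expand(self):
        hits = scan_motifs("ATGCATAC", ["RTRC"])  # R = A/G
        assert [(p) for _, p, _ in hits] == [1, 5]


class TestPairwiseVariants:
    def test_identical_sequences_no_variants(self):
        assert pairwise_variants("ACGTACGT", "ACGTACGT") == []

    def test_single_substitution_located(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:9] + "G" + a[10:]
        assert pairwise_variants(a, b) == [(10, "C", "G")]

    def test_promoter_pair_has_exactly_two_snps(self):
        a, b, truth = generate_promoter_alleles(seed=11)
        variants = pairwise_variants(a, b)
        assert [pos for pos, _, _ in variants] == truth["snp_positions"]
        assert all(ref != alt and "-" not in (ref, alt) for _, ref, alt in variants)

    def test_single_base_deletion_reported_as_gap(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:10] + a[11:]
        variants = pairwise_variants(a, b)
        assert any(alt == "-" for _, _, alt in variants)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_variants("", "ACGT")
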