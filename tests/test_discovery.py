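"""Eight-criterion precursor filter: boundaries, arm/star geometry,
known/novel classification and threshold monotonicity."""

import dataclasses

import pytest

from mirqtl.discovery import (
    CriteriaThresholds,
    PrecursorCandidate,
    apply_criteria,
    au_content,
    classify_known,
    count_star_mismatches,
    extract_precursor_windows,
    locate_arms,
)
from mirqtl.fold import fold
from mirqtl.preprocess import MappedLocus, SmallRNATag
from mirqtl.util import revcomp


@pytest.mark.parametrize(
    "seq,expected", [("AUGC", 50.0), ("AAAA", 100.0), ("GCGC", 0.0), ("ATGC", 50.0)]
)
def test_au_content(seq, expected):
    assert au_content(seq) == expected


def test_au_content_rejects_empty():
    with pytest.raises(ValueError):
        au_content("")


def _passing_candidate(**overrides):
    """A candidate whose measured values satisfy all eight criteria."""
    hairpin = "G" * 10 + "A" * 11 + "G" * 10 + "CAAAAC" + "C" * 10 + "T" * 11 + "C" * 10
    structure = fold(hairpin)
    base = dict(
        chrom="Chr1", start=1, end=len(hairpin), strand="+",
        sequence=hairpin, structure=structure, mature_span=(0, 20),
        star_span=(len(hairpin) - 21, len(hairpin) - 1), read_count=10,
        arm="5p", au_percent=50.0, mfe=-30.0, star_mismatches=0,
        precursor_length=len(hairpin),
    )
    base.update(overrides)
    return PrecursorCandidate(**base)


class TestCriteriaBoundaries:
    def test_all_criteria_pass(self):
        cand = apply_criteria(_passing_candidate())
        assert cand.passed and all(cand.criteria.values())

    def test_low_read_count_fails_only_criterion_1(self):
        cand = apply_criteria(_passing_candidate(read_count=2))
        assert [k for k, v in cand.criteria.items() if not v] == [1]

    def test_read_count_three_is_enough(self):
        assert apply_criteria(_passing_candidate(read_count=3)).criteria[1]

    def test_59nt_precursor_fails_only_criterion_3(self):
        cand = apply_criteria(_passing_candidate(precursor_length=59))
        assert [k for k, v in cand.criteria.items() if not v] == [3]

    def test_mfe_exactly_minus_15_passes(self):
        assert apply_criteria(_passing_candidate(mfe=-15.0)).criteria[8]
        assert not apply_criteria(_passing_candidate(mfe=-14.99)).criteria[8]

    def test_six_star_mismatches_pass_seven_fail(self):
        assert apply_criteria(_passing_candidate(star_mismatches=6)).criteria[6]
        assert not apply_criteria(_passing_candidate(star_mismatches=7)).criteria[6]

    @pytest.mark.parametrize("au,ok", [(30.0, True), (70.0, True), (29.9, False), (70.1, False)])
    def test_au_range_inclusive(self, au, ok):
        assert apply_criteria(_passing_candidate(au_percent=au)).criteria[7] is ok

    def test_loop_spanning_mature_fails_criterion_5(self):
        cand = apply_criteria(_passing_candidate(arm="loop"))
        assert not cand.criteria[5] and cand.criteria[4]


class TestArmGeometry:
    HAIRPIN = "GCGCGCGCGCGCGCGCGCGCG" + "ACAACA" + revcomp("GCGCGCGCGCGCGCGCGCGCG")

    def test_mature_on_5p_arm_with_symmetric_star(self):
        st = fold(self.HAIRPIN)
        arm, star = locate_arms(st, (0, 20))
        assert arm == "5p"
        assert star is not None
        # symmetric perfect stem: star covers the 3' arm (+2 nt overhang capped)
        assert star[1] - star[0] + 1 >= 21
        assert count_star_mismatches(st, (0, 20), star) == 0

    def test_mature_overlapping_terminal_loop_is_loop_spanning(self):
        st = fold(self.HAIRPIN)
        arm, star = locate_arms(st, (15, 35))
        assert arm == "loop" and star is None

    def test_mature_on_3p_arm(self):
        n = len(self.HAIRPIN)
        arm, star = locate_arms(fold(self.HAIRPIN), (n - 21, n - 1))
        assert arm == "3p" and star is not None

    def test_unpaired_mature_has_no_arm(self):
        st = fold("A" * 30)
        assert locate_arms(st, (5, 15)) == ("none", None)


class TestWindows:
    GENOME = {"Chr1": "ACGT" * 2000}

    def _locus(self, start=2001, strand="+"):
        tag = SmallRNATag(self.GENOME["Chr1"][start - 1 : start + 20], {"x": 5})
        return MappedLocus(tag, "Chr1", start, start + 20, strand)

    def test_two_placements_per_window_length(self):
        windows = extract_precursor_windows(self._locus(), self.GENOME, (80, 120), margin=30)
        assert len(windows) == 4
        assert {len(w.sequence) for w in windows} == {80, 120}

    def test_window_contains_tag_at_expected_offset(self):
        w = extract_precursor_windows(self._locus(), self.GENOME, (80,), margin=30)[0]
        m0, m1 = w.mature_span
        tag = self.GENOME["Chr1"][2000:2021]
        assert w.sequence[m0 : m1 + 1] == tag

    def test_clipped_windows_dropped_near_chromosome_start(self):
        windows = extract_precursor_windows(self._locus(start=11), self.GENOME, (200,), margin=10)
        assert len(windows) == 1  # the 3'-side placement would run past the start

    def test_minus_strand_window_is_reverse_complemented(self):
        w = extract_precursor_windows(self._locus(strand="-"), self.GENOME, (80,), margin=30)[0]
        m0, m1 = w.mature_span
        assert w.sequence[m0 : m1 + 1] == revcomp(self.GENOME["Chr1"][2000:2021])


class TestClassifyKnown:
    REFERENCE = {"osa-miR-x": "ACGUACGUACGUACGUACGUA"}

    def test_exact_match_is_known(self):
        status, name, ref = classify_known("ACGTACGTACGTACGTACGTA", self.REFERENCE)
        assert status == "known" and ref == "osa-miR-x"

    def test_single_nt_variant_is_novel(self):
        status, name, ref = classify_known(
            "ACGTACGTACGTACGTACGTT", self.REFERENCE, "Chr2", 1234
        )
        assert status == "novel" and name == "chr2_1234" and ref is None

    def test_empty_reference_gives_novel(self):
        assert classify_known("ACGTACGTACGTACGTACGTA", {})[0] == "novel"


def test_threshold_monotonicity(pipeline_result):
    """Relaxing any single cutoff never shrinks the passing set."""
    candidates = pipeline_result.candidates
    base = CriteriaThresholds()
    relaxed = [
        CriteriaThresholds(min_reads=1),
        CriteriaThresholds(min_precursor_len=40),
        CriteriaThresholds(max_star_mismatches=10),
        CriteriaThresholds(au_min=10.0, au_max=90.0),
        CriteriaThresholds(mfe_max=-5.0),
    ]
    tightened = [
        CriteriaThresholds(min_reads=100),
        CriteriaThresholds(min_precursor_len=80),
        CriteriaThresholds(mfe_max=-40.0),
    ]

    def passing(thresholds):
        out = set()
        for cand in candidates:
            copy = dataclasses.replace(cand, criteria={})
            if apply_criteria(copy, thresholds).passed:
                out.add((copy.chrom, copy.start, copy.end, copy.strand))
        return out

    base_set = passing(base)
    for t in relaxed:
        assert passing(t) >= base_set
    for t in tightened:
        assert passing(t) <= base_set
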