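"""Target prediction and degradome categories: scoring rules, exhaustive
window oracle, slicing geometry and T-plot classification."""

import random

import pytest

from mirqtl.targets import (
    DegradomeProfile,
    build_profile,
    build_profiles_from_sequences,
    categorize_site,
    filter_hits,
    find_target_sites,
    score_duplex,
)
from mirqtl.util import revcomp

MIRNA = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt


def _window_for(mirna, mutate=()):
    """Perfectly complementary window, with optional (mirna_pos, base) edits
    applied to the transcript side opposite the given miRNA position."""
    window = list(revcomp(mirna))
    k = len(mirna)
    for pos, base in mutate:
        window[k - pos] = base
    return "".join(window)


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        score, states = score_duplex(MIRNA, _window_for(MIRNA))
        assert score == 0.0 and set(states) == {"|"}

    def test_gu_wobble_in_core_costs_one(self):
        # miRNA position 5 is G; G:U needs a T opposite it
        assert MIRNA[4] == "G"
        score, states = score_duplex(MIRNA, _window_for(MIRNA, [(5, "T")]))
        assert score == pytest.approx(1.0)  # 0.5 doubled inside positions 2-13
        assert states[len(MIRNA) - 5] == "o"

    def test_two_mismatches_outside_core_cost_two(self):
        window = _window_for(MIRNA, [(15, "C"), (18, "T")])
        # chosen bases are non-complementary, non-wobble at those positions
        score, _ = score_duplex(MIRNA, window)
        assert score == pytest.approx(2.0)

    def test_gap_penalty_doubled_in_core(self):
        score, states = score_duplex(MIRNA, revcomp(MIRNA)[:-1][:20], ("mirna", 10))
        assert score >= 4.0  # gap 2.0 x2 at core position
        assert states.endswith("^")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_duplex(MIRNA, "ACGT")


class TestFindTargetSites:
    def _oracle(self, mirna, transcript, score_max, allow_gaps=True):
        """Enumerate every offset and single-gap variant via score_duplex."""
        k = len(mirna)
        raw = []
        gaps = [None]
        if allow_gaps:
            gaps += [("mirna", p) for p in range(2, k)]
            gaps += [("target", p) for p in range(1, k)]
        for gap in gaps:
            width = k + (0 if gap is None else (1 if gap[0] == "target" else -1))
            for s0 in range(len(transcript) - width + 1):
                score, _ = score_duplex(mirna, transcript[s0 : s0 + width], gap)
                if score <= score_max + 1e-9:
                    raw.append((score, gap is not None, s0 + 1, s0 + width))
        raw.sort(key=lambda r: (r[0], r[1], (r[2], r[3])))
        kept = []
        for score, gapped, a, b in raw:
            if any(a <= kb and b >= ka for _, ka, kb in kept):
                continue
            kept.append((score, a, b))
        return sorted((a, b, round(s, 6)) for s, a, b in kept)

    def test_planted_site_found_at_score_zero(self):
        rng = random.Random(4)
        tx = "".join(rng.choice("ACGT") for _ in range(150)) + revcomp(MIRNA) + "".join(
            rng.choice("ACGT") for _ in range(60)
        )
        sites = find_target_sites(MIRNA, tx, 3.0)
        exact = [s for s in sites if s.score == 0.0]
        assert len(exact) == 1 and exact[0].alignment.span == (151, 171)

    def test_matches_exhaustive_oracle_on_random_transcripts(self):
        rng = random.Random(8)
        for trial in range(4):
            tx = "".join(rng.choice("ACGT") for _ in range(220))
            if trial % 2 == 0:  # plant a near-match to exercise hits
                pos = rng.randrange(40, 120)
                tx = tx[:pos] + revcomp(MIRNA) + tx[pos + 21 :]
            got = sorted(
                (s.alignment.span[0], s.alignment.span[1], round(s.score, 6))
                for s in find_target_sites(MIRNA, tx, 4.5)
            )
            assert got == self._oracle(MIRNA, tx, 4.5)

    def test_score_exactly_at_cutoff_retained(self):
        window = _window_for(MIRNA, [(15, "C"), (18, "T"), (20, "C")])
        assert score_duplex(MIRNA, window)[0] == pytest.approx(3.0)
        sites = find_target_sites(MIRNA, "AAAA" + window + "AAAA", 3.0)
        assert any(s.score == pytest.approx(3.0) for s in sites)

    def test_translation_invariance(self):
        tx = revcomp(MIRNA)
        base = find_target_sites(MIRNA, "A" * 10 + tx + "A" * 10, 1.0)[0]
        shifted = find_target_sites(MIRNA, "A" * 17 + tx + "A" * 3, 1.0)[0]
        assert shifted.alignment.span[0] - base.alignment.span[0] == 7
        assert shifted.cleavage_position - base.cleavage_position == 7
        assert shifted.score == base.score


class TestCleavageGeometry:
    def test_site_at_101_121_cleaves_at_112(self):
        tx = "A" * 100 + revcomp(MIRNA) + "A" * 50
        site = find_target_sites(MIRNA, tx, 0.5)[0]
        assert site.alignment.span == (101, 121)
        assert site.cleavage_position == 112

    def test_two_sites_get_distinct_positions(self):
        tx = "C" * 30 + revcomp(MIRNA) + "C" * 40 + revcomp(MIRNA) + "C" * 30
        sites = find_target_sites(MIRNA, tx, 0.5)
        assert len(sites) == 2
        assert sites[0].cleavage_position != sites[1].cleavage_position


class TestProfiles:
    def test_counts_accumulate_at_position(self):
        prof = build_profile([(112, 1)] * 5, "t1")
        assert prof.counts == {112: 5}

    def test_no_tags_empty_profile(self):
        assert build_profile([], "t1").counts == {}

    def test_position_outside_transcript_rejected(self):
        with pytest.raises(ValueError):
            build_profile([(500, 1)], "t1", transcript_length=300)

    def test_multimapping_tag_counted_in_both_and_flagged(self):
        transcripts = {"t1": "AAACCCGGGTTTACGTACGT", "t2": "TTTCCCGGGTTTAAAAAAAA"}
        profiles, multi = build_profiles_from_sequences(["CCCGGGTTT"], transcripts)
        assert profiles["t1"].counts == {4: 1} and profiles["t2"].counts == {4: 1}
        assert multi == {"CCCGGGTTT"}


class TestCategories:
    def _prof(self, counts):
        return DegradomeProfile("t", "lib", counts)

    def test_unique_maximum_is_category_0(self):
        assert categorize_site(self._prof({112: 10, 50: 1, 80: 1}), 112) == 0

    def test_shared_maximum_is_category_1(self):
        assert categorize_site(self._prof({112: 10, 300: 10, 50: 1}), 112) == 1

    def test_single_read_is_category_4_even_at_maximum(self):
        assert categorize_site(self._prof({112: 1, 50: 1}), 112) == 4

    def test_above_median_below_max_is_category_2(self):
        prof = self._prof({112: 5, 10: 10, 20: 1, 30: 1, 40: 2})
        assert categorize_site(prof, 112) == 2

    def test_at_or_below_median_is_category_3(self):
        prof = self._prof({112: 2, 10: 10, 20: 8, 30: 2, 40: 2})
        assert categorize_site(prof, 112) == 3

    def test_zero_count_is_no_hit(self):
        assert categorize_site(self._prof({50: 3, 80: 2}), 112) is None

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            categorize_site(self._prof({}), 112)

    def test_categories_partition_nonzero_positions(self):
        prof = self._prof({10: 10, 20: 7, 30: 3, 40: 1, 50: 2, 60: 10})
        cats = {pos: categorize_site(prof, pos) for pos in prof.counts}
        assert all(c in (0, 1, 2, 3, 4) for c in cats.values())
        assert cats[10] == cats[60] == 1  # tied maxima


class TestFilterHits:
    def _site(self):
        tx = "A" * 40 + revcomp(MIRNA) + "A" * 40
        return find_target_sites(MIRNA, tx, 0.5)[0]

    def test_category_3_everywhere_dropped(self):
        site = self._site()
        assert filter_hits({site: {f"l{i}": 3 for i in range(5)}}) == []

    def test_category_0_in_six_of_nine_kept_with_support(self):
        site = self._site()
        cats = {f"l{i}": (0 if i < 6 else 3) for i in range(9)}
        hits = filter_hits({site: cats})
        assert len(hits) == 1 and hits[0].n_supporting_libraries == 6

    def test_min_libraries_two_drops_single_support(self):
        site = self._site()
        assert filter_hits({site: {"l1": 0, "l2": 3}}, min_libraries=2) == []
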