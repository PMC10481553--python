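"""miRNA target prediction and degradome (PARE) validation.

One complementarity-scoring engine stands in for the plant target
predictors: penalties are summed over the miRNA:mRNA duplex (mismatch 1.0,
G:U wobble 0.5, gap 2.0, each doubled inside the functionally critical
miRNA positions 2-13 counted from the 5' end) and a site is reported when
the total is at or below the score cutoff (default 3.0). Two
parameterizations are exposed — the default (up to one bulge on either
strand) and a stricter no-gap variant — so multi-tool consensus logic can
be preserved by tagging which parameterization found each site.

Degradome validation piles 5'-end tag counts onto transcripts and
classifies each predicted cleavage position into T-plot categories:

    4  exactly one read at the site;
    0  the site count is the unique maximum of the transcript profile;
    1  the site count ties the maximum;
    2  above the median of nonzero positions but below the maximum;
    3  any remaining nonzero count;
    no category when the site has no signal.

The slice site is the transcript base paired to miRNA position 10, kept as
a single integer coordinate."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .util import normalize_seq

GAP_PENALTY = 2.0
MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
CORE_RANGE = (2, 13)  # miRNA positions with doubled penalties, inclusive
DEFAULT_SCORE_MAX = 3.0
DEFAULT_KEPT_CATEGORIES = (0, 1, 2)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}
# penalty[mirna_base][transcript_base]
_PAIR_PENALTY = np.full((4, 4), MISMATCH_PENALTY)
for _g, _t in ((0, 3), (3, 0), (2, 1), (1, 2)):  # Watson-Crick
    _PAIR_PENALTY[_g, _t] = 0.0
for _g, _t in ((2, 3), (3, 2)):  # G:U wobble (DNA letters G:T)
    _PAIR_PENALTY[_g, _t] = WOBBLE_PENALTY


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[b] for b in normalize_seq(seq)], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character {exc} in sequence") from exc


def position_weight(pos: int) -> float:
    return 2.0 if CORE_RANGE[0] <= pos <= CORE_RANGE[1] else 1.0


@dataclass(frozen=True)
class DuplexAlignment:
    """A scored miRNA:transcript duplex over one transcript window.

    `states` is one symbol per alignment column, transcript 5'->3': '|'
    match, 'o' G:U wobble, 'x' mismatch, '-' bulged transcript base,
    '^' bulged (skipped) miRNA base marker. `gap` is None, ("mirna", p) or
    ("target", p) with p the miRNA position at/after the bulge.
    """

    mirna_id: str
    transcript_id: str
    span: tuple[int, int]  # 1-based inclusive transcript coordinates
    states: str
    penalty_score: float
    gap: tuple[str, int] | None = None


@dataclass(frozen=True)
class TargetSite:
    alignment: DuplexAlignment
    cleavage_position: int
    cleavage_flagged: bool = False
    predicted_by: frozenset[str] = frozenset()

    @property
    def mirna_id(self) -> str:
        return self.alignment.mirna_id

    @property
    def transcript_id(self) -> str:
        return self.alignment.transcript_id

    @property
    def score(self) -> float:
        return self.alignment.penalty_score

    def tagged(self, *tags: str) -> "TargetSite":
        return replace(self, predicted_by=self.predicted_by | frozenset(tags))


def _alignment_columns(k: int, gap: tuple[str, int] | None) -> list[int]:
    """miRNA position per column (transcript 5'->3'), 0 = bulged base."""
    cols = list(range(k, 0, -1))
    if gap is None:
        return cols
    kind, gp = gap
    if kind == "mirna":
        if not 2 <= gp <= k - 1:
            raise ValueError("miRNA bulge position must be interior")
        cols.remove(gp)
    elif kind == "target":
        if not 1 <= gp <= k - 1:
            raise ValueError("target bulge position out of range")
        cols.insert(cols.index(gp), 0)
    else:
        raise ValueError(f"unknown gap kind: {kind}")
    return cols


def score_duplex(
    mirna: str, window: str, gap: tuple[str, int] | None = None
) -> tuple[float, str]:
    """Penalty score and per-column states for one duplex alignment.

    The transcript window is given 5'->3' and pairs the miRNA
    antiparallel (miRNA position 1 against the window's 3' end). A gap
    adds GAP_PENALTY at the weight of its miRNA position.
    """
    m = _encode(mirna)
    t = _encode(window)
    k = len(m)
    cols = _alignment_columns(k, gap)
    expected = len(cols)
    if len(t) != expected:
        raise ValueError(f"window length {len(t)} does not fit alignment ({expected})")
    score = 0.0
    states = []
    for base, pos in zip(t, cols):
        if pos == 0:  # bulged transcript base
            score += GAP_PENALTY * position_weight(gap[1])
            states.append("-")
            continue
        pen = _PAIR_PENALTY[m[pos - 1], base]
        score += pen * position_weight(pos)
        states.append("|" if pen == 0.0 else ("o" if pen == WOBBLE_PENALTY else "x"))
    if gap is not None and gap[0] == "mirna":
        score += GAP_PENALTY * position_weight(gap[1])
        states.append("^")
    return score, "".join(states)


def _site_from_alignment(
    mirna_id: str, transcript_id: str, start1: int, cols: Sequence[int],
    score: float, states: str, gap,
) -> TargetSite:
    span = (start1, start1 + len([c for c in cols]) - 1)
    flagged = False
    if 10 in cols:
        cleav = start1 + cols.index(10)
    else:  # miRNA position 10 bulged out: nearest paired partner, flagged
        nearest = 11 if 11 in cols else 9
        cleav = start1 + cols.index(nearest)
        flagged = True
    aln = DuplexAlignment(mirna_id, transcript_id, span, states, score, gap)
    return TargetSite(aln, cleav, flagged)


def find_target_sites(
    mirna: str,
    transcript: str,
    score_max: float = DEFAULT_SCORE_MAX,
    allow_gaps: bool = True,
    mirna_id: str = "mirna",
    transcript_id: str = "transcript",
) -> list[TargetSite]:
    """All target windows with penalty <= score_max (inclusive).

    Scans every offset with zero gaps and, when allowed, every single-bulge
    variant on either strand. Overlapping hits for the same miRNA are
    deduplicated to the best-scoring site (ties: ungapped first, then
    leftmost).
    """
    m = _encode(mirna)
    t = _encode(transcript)
    k = len(m)
    if len(t) < k:
        raise ValueError("transcript shorter than miRNA")
    gaps: list[tuple[str, int] | None] = [None]
    if allow_gaps:
        gaps += [("mirna", p) for p in range(2, k)]
        gaps += [("target", p) for p in range(1, k)]
    raw: list[TargetSite] = []
    for gap in gaps:
        cols = _alignment_columns(k, gap)
        width = len(cols)
        if len(t) < width:
            continue
        colarr = np.array(cols)
        live = colarr > 0
        weights = np.where(
            (colarr >= CORE_RANGE[0]) & (colarr <= CORE_RANGE[1]), 2.0, 1.0
        )
        const = 0.0
        if gap is not None:
            const = GAP_PENALTY * position_weight(gap[1])
        mirna_idx = np.where(live, colarr - 1, 0)
        pen_lut = _PAIR_PENALTY[m[mirna_idx]]  # (width, 4)
        windows = np.lib.stride_tricks.sliding_window_view(t, width)
        pens = np.take_along_axis(pen_lut[None, :, :], windows[:, :, None], axis=2)[:, :, 0]
        scores = (pens * (weights * live)[None, :]).sum(axis=1) + const
        for s0 in np.nonzero(scores <= score_max + 1e-9)[0]:
            score, states = score_duplex(
                mirna, transcript[s0 : s0 + width], gap
            )
            raw.append(
                _site_from_alignment(
                    mirna_id, transcript_id, int(s0) + 1, cols, score, states, gap
                )
            )
    raw.sort(
        key=lambda s: (s.score, 0 if s.alignment.gap is None else 1, s.alignment.span)
    )
    kept: list[TargetSite] = []
    for site in raw:
        a, b = site.alignment.span
        if any(a <= s.alignment.span[1] and b >= s.alignment.span[0] for s in kept):
            continue
        kept.append(site)
    kept.sort(key=lambda s: s.alignment.span)
    return kept


def cleavage_position(site: TargetSite) -> int:
    """Transcript coordinate sliced opposite miRNA position 10."""
    return site.cleavage_position


@dataclass
class DegradomeProfile:
    """Per-transcript 5'-end read counts for one degradome library."""

    transcript_id: str
    library_id: str
    counts: dict[int, int] = field(default_factory=dict)

    def count_at(self, position: int) -> int:
        return self.counts.get(position, 0)


@dataclass(frozen=True)
class DegradomeHit:
    site: TargetSite
    categories: tuple[tuple[str, int], ...]  # (library, category) pairs
    n_supporting_libraries: int


def build_profile(
    tag_positions: Iterable[tuple[int, int]],
    transcript_id: str,
    library_id: str = "lib",
    transcript_length: int | None = None,
) -> DegradomeProfile:
    """Accumulate (position, count) 5'-end records into a profile."""
    counts: dict[int, int] = {}
    for pos, cnt in tag_positions:
        if pos < 1 or (transcript_length is not None and pos > transcript_length):
            raise ValueError(f"degradome position {pos} outside transcript")
        if cnt < 0:
            raise ValueError("negative degradome count")
        if cnt:
            counts[pos] = counts.get(pos, 0) + cnt
    return DegradomeProfile(transcript_id, library_id, counts)


def build_profiles_from_sequences(
    tags: Iterable[str], transcripts: Mapping[str, str], library_id: str = "lib"
) -> tuple[dict[str, DegradomeProfile], set[str]]:
    """Map degradome tag sequences to transcripts by exact match.

    The 5' end of each occurrence increments that position; a tag matching
    several transcripts is counted in each and flagged multi-mapped.
    """
    profiles = {
        tid: DegradomeProfile(tid, library_id) for tid in transcripts
    }
    multimapped: set[str] = set()
    for tag in tags:
        tag = normalize_seq(tag)
        hit_tids = []
        for tid in sorted(transcripts):
            seq = transcripts[tid]
            start = seq.find(tag)
            found = False
            while start != -1:
                profiles[tid].counts[start + 1] = profiles[tid].counts.get(start + 1, 0) + 1
                found = True
                start = seq.find(tag, start + 1)
            if found:
                hit_tids.append(tid)
        if len(hit_tids) > 1:
            multimapped.add(tag)
    return {t: p for t, p in profiles.items() if p.counts}, multimapped


def categorize_site(profile: DegradomeProfile, cleavage_position: int) -> int | None:
    """T-plot category of the degradome signal at a predicted slice site.

    None (no hit) when the site has zero count; categories follow the
    docstring at the top of the module. The median is taken over the
    nonzero positions of the transcript profile.
    """
    if not profile.counts:
        raise ValueError("empty degradome profile")
    c = profile.count_at(cleavage_position)
    if c == 0:
        return None
    if c == 1:
        return 4
    values = list(profile.counts.values())
    cmax = max(values)
    if c == cmax:
        return 0 if values.count(cmax) == 1 else 1
    if c > median(values):
        return 2
    return 3


def filter_hits(
    site_categories: Mapping[TargetSite, Mapping[str, int | None]],
    kept_categories: Sequence[int] = DEFAULT_KEPT_CATEGORIES,
    min_libraries: int = 1,
) -> list[DegradomeHit]:
    """Validated sites: category in kept_categories in >= min_libraries.

    Library support counts only the libraries whose category is kept.
    """
    kept = set(kept_categories)
    out: list[DegradomeHit] = []
    for site, per_lib in site_categories.items():
        cats = tuple(
            sorted((lib, cat) for lib, cat in per_lib.items() if cat is not None)
        )
        support = sum(1 for _, cat in cats if cat in kept)
        if support >= min_libraries:
            out.append(DegradomeHit(site, cats, support))
    out.sort(key=lambda h: (h.site.mirna_id, h.site.transcript_id, h.site.alignment.span))
    return out
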