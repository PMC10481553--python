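"""miRNA precursor calling: window excision, folding, the eight-criterion
filter, and known/novel classification.

A mapped small-RNA tag nominates candidate precursors: genomic windows of
several configured lengths around the tag are excised, folded with the
default engine, trimmed to the hairpin extent that encloses the tag, and
refolded. Each trimmed precursor is then scored against eight annotation
criteria used for plant miRNA precursors:

1. the supporting tag has at least 3 reads;
2. the tag maps to the precursor with an exact sequence match (structural
   here: candidates only arise from exact-mapped loci);
3. the precursor is at least 60 nt long;
4. the precursor folds into a hairpin;
5. the tag occupies a single arm of the hairpin (not the terminal loop);
6. the opposing (star) strand shows no more than 6 mismatches, where a
   mismatch is an unpaired mature position and G:U counts as paired;
7. the A+U content lies between 30 and 70 percent;
8. the minimum free energy is at or below -15 kcal/mol.

All thresholds are inclusive where the wording is inclusive ("at least",
"no more than", "less than or equal to"). The star strand follows the
canonical Dicer geometry: the segment pairing the mature arm, extended by a
2-nt 3' overhang.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .fold import HairpinStructure, fold
from .preprocess import MappedLocus
from .util import normalize_seq, revcomp

DEFAULT_WINDOW_LENGTHS = (80, 120, 200, 250)
DEFAULT_WINDOW_MARGIN = 30

CRITERION_NAMES = {
    1: "min_read_count",
    2: "exact_match_mapping",
    3: "min_precursor_length",
    4: "hairpin_formed",
    5: "single_arm",
    6: "max_star_mismatches",
    7: "au_content_range",
    8: "mfe_threshold",
}


@dataclass(frozen=True)
class CriteriaThresholds:
    min_reads: int = 3
    min_precursor_len: int = 60
    max_star_mismatches: int = 6
    au_min: float = 30.0
    au_max: float = 70.0
    mfe_max: float = -15.0
    read_count_mode: str = "sum"  # "sum" across libraries or "per-library" max


@dataclass
class PrecursorCandidate:
    """A trimmed, folded precursor candidate with per-criterion verdicts."""

    chrom: str
    start: int  # 1-based inclusive genomic span of the trimmed precursor
    end: int
    strand: str
    sequence: str
    structure: HairpinStructure | None
    mature_span: tuple[int, int]  # 0-based inclusive, within `sequence`
    star_span: tuple[int, int] | None
    read_count: int
    arm: str = "none"  # 5p | 3p | loop | none
    au_percent: float = 0.0
    mfe: float = 0.0
    star_mismatches: int = 0
    precursor_length: int = 0
    criteria: dict[int, bool] = field(default_factory=dict)
    passed: bool = False
    locus: MappedLocus | None = None

    @property
    def mature_sequence(self) -> str:
        s, e = self.mature_span
        return self.sequence[s : e + 1]


@dataclass(frozen=True)
class MiRNACall:
    name: str
    mature_sequence: str
    precursor: PrecursorCandidate
    status: str  # "known" | "novel"
    reference_name: str | None = None


@dataclass(frozen=True)
class Window:
    """An excised genomic window in folding (5'->3' transcript) orientation."""

    chrom: str
    gstart: int  # 1-based inclusive genomic coordinates of the window
    gend: int
    strand: str
    sequence: str
    mature_span: tuple[int, int]  # 0-based inclusive, in `sequence`


def au_content(sequence: str) -> float:
    """Percent A+U (A+T after normalization) of a sequence."""
    seq = normalize_seq(sequence)
    if not seq:
        raise ValueError("empty sequence")
    return 100.0 * (seq.count("A") + seq.count("T")) / len(seq)


def extract_precursor_windows(
    locus: MappedLocus,
    genome: Mapping[str, str],
    window_lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
    margin: int = DEFAULT_WINDOW_MARGIN,
) -> list[Window]:
    """Candidate windows around a mapped tag, in both placements.

    For each window length L the tag is placed toward the window's 5' side
    (margin nt of upstream context) and toward its 3' side. Windows that
    would run past a chromosome end are dropped. Minus-strand loci yield
    reverse-complemented window sequences so folding always sees the
    transcript orientation.
    """
    chrom_seq = genome[locus.chrom]
    n = len(chrom_seq)
    taglen = locus.end - locus.start + 1
    out: list[Window] = []
    for L in window_lengths:
        if L < taglen + margin:
            continue
        for placement in ("5p", "3p"):
            on_five = placement == "5p"
            if (locus.strand == "+") == on_five:
                gstart = locus.start - margin
                gend = gstart + L - 1
            else:
                gend = locus.end + margin
                gstart = gend - L + 1
            if gstart < 1 or gend > n:
                continue
            seq = chrom_seq[gstart - 1 : gend]
            if locus.strand == "+":
                m0 = locus.start - gstart
            else:
                seq = revcomp(seq)
                m0 = gend - locus.end
            out.append(Window(locus.chrom, gstart, gend, locus.strand, seq, (m0, m0 + taglen - 1)))
    return out


def trim_to_hairpin(
    structure: HairpinStructure, mature_span: tuple[int, int]
) -> tuple[int, int] | None:
    """Extent (0-based inclusive) of the stem-loop hosting the mature tag.

    Finds the outermost pair touching the mature region, then extends
    outward through the enclosing helix as long as each enclosing pair has
    a single branch (stacks, bulges and internal loops continue the stem;
    a multiloop junction or the exterior ends it). This excises the local
    hairpin the way precursor callers do, rather than the whole folded
    window, which for long windows is typically a large branched
    structure. None when no pair touches or encloses the mature region.
    """
    m0, m1 = mature_span
    pairs = sorted(structure.pairs)
    if not pairs:
        return None
    # nesting tree: parent/children of each pair
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        parent[p] = stack[-1] if stack else None
        if stack:
            children[stack[-1]].append(p)
        stack.append(p)
    involved = [p for p in pairs if (m0 <= p[0] <= m1) or (m0 <= p[1] <= m1)]
    if involved:
        lo = min(p[0] for p in involved)
        hi = max(p[1] for p in involved)
        anchor = next((p for p in involved if p[0] == lo and p[1] == hi), None)
        if anchor is None:
            # mature pairs into separate branches: no single stem-loop
            return min(lo, m0), max(hi, m1)
    else:
        # mature unpaired: innermost pair enclosing it, if any
        anchor = None
        for p in pairs:
            if p[0] < m0 and p[1] > m1:
                if anchor is None or (p[0] > anchor[0] and p[1] < anchor[1]):
                    anchor = p
        if anchor is None:
            return None
    while parent[anchor] is not None and len(children[parent[anchor]]) == 1:
        anchor = parent[anchor]
    return min(anchor[0], m0), max(anchor[1], m1)


def locate_arms(
    structure: HairpinStructure, mature_span: tuple[int, int]
) -> tuple[str, tuple[int, int] | None]:
    """Assign the mature tag to a hairpin arm and derive the star span.

    Returns (arm, star_span): arm is "5p" when every partner of a paired
    mature base lies 3' of the tag, "3p" when 5', "loop" when partners
    straddle or fall inside the tag (the tag spans the terminal loop), and
    "none" when the tag is entirely unpaired. The star span runs from the
    partner of the tag's 3'-most paired base to the partner of its 5'-most
    paired base plus the canonical 2-nt 3' overhang.
    """
    m0, m1 = mature_span
    paired = [(p, structure.partner(p)) for p in range(m0, m1 + 1) if structure.partner(p) >= 0]
    if not paired:
        return "none", None
    partners = [q for _, q in paired]
    if all(q > m1 for q in partners):
        arm = "5p"
    elif all(q < m0 for q in partners):
        arm = "3p"
    else:
        return "loop", None
    s_p = min(p for p, _ in paired)  # 5'-most paired mature base
    e_p = max(p for p, _ in paired)  # 3'-most paired mature base
    star_lo = structure.partner(e_p)
    star_hi = structure.partner(s_p) + 2
    n = len(structure.sequence)
    return arm, (max(0, min(star_lo, star_hi)), min(n - 1, max(star_lo, star_hi)))


def count_star_mismatches(
    structure: HairpinStructure,
    mature_span: tuple[int, int],
    star_span: tuple[int, int] | None,
) -> int:
    """Mature positions not paired (WC or G:U) into the star segment.

    With no locatable star (loop-spanning or unpaired tag) only unpaired
    mature positions count, which keeps the verdict well-defined for
    degenerate hairpins.
    """
    m0, m1 = mature_span
    n_mm = 0
    for p in range(m0, m1 + 1):
        q = structure.partner(p)
        if q < 0:
            n_mm += 1
        elif star_span is not None and not (star_span[0] <= q <= star_span[1]):
            n_mm += 1
    return n_mm


def apply_criteria(
    candidate: PrecursorCandidate, thresholds: CriteriaThresholds = CriteriaThresholds()
) -> PrecursorCandidate:
    """Fill the eight per-criterion verdicts and the overall pass flag."""
    t = thresholds
    has_hairpin = candidate.structure is not None and len(candidate.structure.pairs) > 0
    verdicts = {
        1: candidate.read_count >= t.min_reads,
        2: True,  # candidates only arise from exact-match mapped loci
        3: candidate.precursor_length >= t.min_precursor_len,
        4: has_hairpin and candidate.arm != "none",
        5: candidate.arm in ("5p", "3p"),
        6: candidate.star_mismatches <= t.max_star_mismatches,
        7: t.au_min <= candidate.au_percent <= t.au_max,
        8: candidate.mfe <= t.mfe_max,
    }
    candidate.criteria = verdicts
    candidate.passed = all(verdicts.values())
    return candidate


def _excise_structure(
    wstruct: HairpinStructure, lo: int, hi: int
) -> HairpinStructure:
    """Substructure of a window fold restricted to [lo, hi] (0-based incl.).

    The excised stem-loop keeps the pairings it has in the window's MFE
    structure; its energy is the loop-decomposition energy of those pairs
    evaluated standalone. This mirrors precursor excision: the hairpin is
    judged as it folds in context, not refolded in isolation.
    """
    from .fold import structure_energy  # local import to avoid cycle at module load

    seq = wstruct.sequence[lo : hi + 1]
    pairs = [
        (i - lo, j - lo) for i, j in wstruct.pairs if lo <= i and j <= hi
    ]
    n = len(seq)
    pt = [0] * (n + 1)
    db = ["."] * n
    for i, j in pairs:
        pt[i + 1] = j + 1
        pt[j + 1] = i + 1
        db[i] = "("
        db[j] = ")"
    energy = structure_energy(seq, pairs) if pairs else 0.0
    return HairpinStructure(seq, "".join(db), tuple(pt), round(float(energy), 6))


def evaluate_window(
    window: Window, read_count: int, thresholds: CriteriaThresholds = CriteriaThresholds(),
    locus: MappedLocus | None = None,
) -> PrecursorCandidate:
    """Fold one window, excise the mature-anchored stem-loop, score criteria."""
    wstruct = fold(window.sequence)
    span = trim_to_hairpin(wstruct, window.mature_span)
    if span is not None:
        lo, hi = span
        structure = _excise_structure(wstruct, lo, hi)
        prec_seq = structure.sequence
        mspan = (window.mature_span[0] - lo, window.mature_span[1] - lo)
    else:
        lo, hi = 0, len(window.sequence) - 1
        prec_seq = window.sequence
        structure = wstruct
        mspan = window.mature_span
    if window.strand == "+":
        gstart, gend = window.gstart + lo, window.gstart + hi
    else:
        gstart, gend = window.gend - hi, window.gend - lo
    arm, star_span = locate_arms(structure, mspan)
    cand = PrecursorCandidate(
        chrom=window.chrom,
        start=gstart,
        end=gend,
        strand=window.strand,
        sequence=prec_seq,
        structure=structure,
        mature_span=mspan,
        star_span=star_span,
        read_count=read_count,
        arm=arm,
        au_percent=au_content(prec_seq),
        mfe=structure.mfe,
        star_mismatches=count_star_mismatches(structure, mspan, star_span),
        precursor_length=len(prec_seq),
        locus=locus,
    )
    return apply_criteria(cand, thresholds)


def _candidate_read_count(locus: MappedLocus, mode: str) -> int:
    if mode == "per-library":
        return max(locus.tag.counts.values(), default=0)
    return locus.tag.total_count


def evaluate_locus(
    locus: MappedLocus,
    genome: Mapping[str, str],
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    window_lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
    margin: int = DEFAULT_WINDOW_MARGIN,
) -> PrecursorCandidate | None:
    """Best candidate for one mapped locus across all windows.

    Multiple windows for one locus never yield two candidates: ties are
    resolved by lowest MFE, then shortest precursor, then leftmost window,
    giving deterministic output.
    """
    windows = extract_precursor_windows(locus, genome, window_lengths, margin)
    if not windows:
        return None
    rc = _candidate_read_count(locus, thresholds.read_count_mode)
    cands = [evaluate_window(w, rc, thresholds, locus) for w in windows]
    cands.sort(key=lambda c: (c.mfe, c.precursor_length, c.start))
    return cands[0]


def classify_known(
    mature_sequence: str,
    reference: Mapping[str, str],
    chrom: str = "chrX",
    start: int = 0,
    libtag: str = "",
) -> tuple[str, str, str | None]:
    """(status, name, reference_name) for a mature sequence.

    Known requires exact sequence identity with a reference mature after
    U/T normalization; anything else is novel, named by its locus in the
    `chr<c>_<start><libtag>` style.
    """
    query = normalize_seq(mature_sequence)
    for name in sorted(reference):
        if normalize_seq(reference[name]) == query:
            return "known", name, name
    return "novel", f"{chrom.lower()}_{start}{libtag}", None


def discover_mirnas(
    loci: Iterable[MappedLocus],
    genome: Mapping[str, str],
    reference: Mapping[str, str] | None = None,
    thresholds: CriteriaThresholds = CriteriaThresholds(),
    window_lengths: Sequence[int] = DEFAULT_WINDOW_LENGTHS,
    margin: int = DEFAULT_WINDOW_MARGIN,
) -> tuple[list[MiRNACall], list[PrecursorCandidate]]:
    """Evaluate every mapped locus; return passing calls and all candidates.

    Candidates are deduplicated on (chrom, strand, mature genomic span).
    With an empty reference every call is novel.
    """
    reference = reference or {}
    best: dict[tuple, PrecursorCandidate] = {}
    for locus in loci:
        cand = evaluate_locus(locus, genome, thresholds, window_lengths, margin)
        if cand is None:
            continue
        key = (locus.chrom, locus.strand, locus.start, locus.end)
        prev = best.get(key)
        if prev is None or (cand.mfe, cand.precursor_length, cand.start) < (
            prev.mfe, prev.precursor_length, prev.start
        ):
            best[key] = cand
    candidates = sorted(
        best.values(), key=lambda c: (c.chrom, c.start, c.end, c.strand)
    )
    calls: list[MiRNACall] = []
    for cand in candidates:
        if not cand.passed:
            continue
        status, name, ref_name = classify_known(
            cand.mature_sequence, reference, cand.chrom,
            cand.locus.start if cand.locus else cand.start,
        )
        calls.append(MiRNACall(name, cand.mature_sequence, cand, status, ref_name))
    return calls, candidates
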