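"""Synthetic study generator: every input the pipeline consumes, with
planted ground truth.

The generator emulates the study design end to end at desk scale: a small
random genome; hairpin precursors planted so that true loci satisfy all
eight annotation criteria under the default folding engine while each decoy
class violates exactly one designated criterion; twelve small-RNA libraries
(3 genotypes x 2 conditions x 2 replicates) with condition-dependent tag
abundances; gene models placed inside/outside affinely rescaled copies of
the three qDTY intervals; degradome libraries with cleavage peaks at the
planted slicing positions; and a drought-inventory gene subset.

Two criteria cannot be violated in isolation and therefore have no decoy
class: exact-match mapping (criterion 2) is structural — a tag that does
not map exactly never nominates a precursor — and hairpin formation
(criterion 4) cannot fail while the -15 kcal/mol stability bound passes,
because a foldless candidate has zero free energy.

Planted loci are self-verified: after writing a hairpin and its flanks into
the genome the generator runs the real discovery evaluation and
re-randomizes (seeded, bounded) until the criteria vector matches the
designated class, so the planted truth is guaranteed under the default
engine rather than assumed. Every design pairs at least two mature bases
through G:U so the mature's reverse complement never occurs verbatim in
the star arm (which would create a spurious minus-strand locus).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .de import LibraryMeta
from .discovery import CriteriaThresholds, evaluate_locus
from .io import write_fasta, write_fastq, write_gff3, write_tsv
from .preprocess import MappedLocus, SmallRNATag
from .qtl import DEFAULT_QTL_INTERVALS, QTLInterval
from .util import revcomp

MATURE_LEN = 21
FLANK = 250  # inert A/C context around each planted hairpin; spans the
# candidate-window reach so planted stem-loops cannot pair into random genome
SLOT_STEP = 900  # spacing between planted loci; keeps candidate windows disjoint

# Approximate rice chromosome lengths used to rescale the printed QTL
# intervals onto desk-scale synthetic chromosomes.
REAL_CHROM_LENGTHS = {"Chr1": 43_270_923, "Chr3": 36_413_819, "Chr12": 27_531_856}

DEFAULT_LIBRARY_DESIGN = tuple(
    (g, c, r)
    for g in ("IR20", "SD", "VD")
    for c in ("control", "drought")
    for r in (1, 2)
)


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 42
    n_chromosomes: int = 3
    chrom_length: int = 60_000
    n_true_precursors: int = 20
    n_decoys_per_criterion: int = 5
    decoy_criteria: tuple[int, ...] = (1, 3, 5, 6, 7, 8)
    n_genes: int = 100
    gene_length: int = 300
    qtl_fraction: float = 0.3
    library_design: tuple[tuple[str, str, int], ...] = DEFAULT_LIBRARY_DESIGN
    adapter_sequence: str = "TGGAATTCTCGGGTGCCAAGG"
    de_fraction: float = 0.4
    planted_log2fc_range: tuple[float, float] = (2.0, 3.0)
    mean_count_range: tuple[float, float] = (50.0, 200.0)
    decoy_read_count: int = 12
    degradome_peak_height: int = 20
    n_degradome_libraries: int = 9
    degradome_background_rate: float = 0.005
    n_background_tags: int = 30
    inventory_fraction: float = 0.28
    known_fraction: float = 0.5
    low_quality_fraction: float = 0.05
    targets_per_mirna: int = 2

    def __post_init__(self) -> None:
        if self.chrom_length < 5_000:
            raise ValueError("chrom_length too small for planted loci")
        if not self.library_design:
            raise ValueError("library_design must be non-empty")
        if not 0 <= self.qtl_fraction <= 1:
            raise ValueError("qtl_fraction must be in [0, 1]")

    @property
    def library_meta(self) -> list[LibraryMeta]:
        return [
            LibraryMeta(f"{g}_{c}_r{r}", g, c, r) for g, c, r in self.library_design
        ]


@dataclass
class PlantedPrecursor:
    name: str
    mature_sequence: str
    chrom: str
    start: int  # hairpin genomic span, 1-based inclusive
    end: int
    mature_start: int
    mature_end: int
    base_mean: float = 100.0
    planted_log2fc: float = 0.0
    is_known: bool = False


@dataclass
class PlantedDecoy:
    name: str
    mature_sequence: str
    chrom: str
    start: int
    end: int
    mature_start: int
    mature_end: int
    violated_criterion: int = 0


@dataclass
class TargetPair:
    mirna_name: str
    gene_id: str
    site_offset: int  # 0-based offset of the complementary site in the transcript
    cleavage_position: int  # 1-based transcript coordinate opposite miRNA pos 10
    support_libraries: tuple[int, ...] = ()


@dataclass
class GroundTruth:
    true_mirnas: list[PlantedPrecursor] = field(default_factory=list)
    decoys: list[PlantedDecoy] = field(default_factory=list)
    true_target_pairs: list[TargetPair] = field(default_factory=list)
    qtl_resident_genes: set[str] = field(default_factory=set)
    inventory_genes: set[str] = field(default_factory=set)
    qtl_intervals: tuple[QTLInterval, ...] = ()
    qtl_scale: dict = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict[str, str]
    truth: GroundTruth
    genes: pd.DataFrame
    transcripts: dict[str, str]
    counts: pd.DataFrame  # true-miRNA counts per library
    reads: dict[str, list[tuple[str, str, str]]]
    degradome: dict[str, pd.DataFrame]
    reference_matures: dict[str, str]

    @property
    def library_meta(self) -> list[LibraryMeta]:
        return self.config.library_meta


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _rand_bases(rng, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def chromosome_names(config: SyntheticConfig) -> list[str]:
    base = ["Chr1", "Chr3", "Chr12"]
    names = base[: config.n_chromosomes]
    for k in range(len(names), config.n_chromosomes):
        names.append(f"Chr{k + 20}")
    return names


def scaled_qtl_intervals(
    config: SyntheticConfig,
) -> tuple[tuple[QTLInterval, ...], dict]:
    """Printed qDTY intervals affinely rescaled onto the synthetic genome."""
    chroms = set(chromosome_names(config))
    scaled, mapping = [], {}
    for iv in DEFAULT_QTL_INTERVALS:
        if iv.chrom not in chroms:
            continue
        factor = config.chrom_length / REAL_CHROM_LENGTHS[iv.chrom]
        s = max(1, round(iv.start * factor))
        e = min(config.chrom_length, round(iv.end * factor))
        scaled.append(QTLInterval(iv.name, iv.chrom, s, e, iv.flanking_markers))
        mapping[iv.name] = {
            "factor": factor,
            "real": (iv.start, iv.end),
            "synthetic": (s, e),
        }
    return tuple(scaled), mapping


# ---------------------------------------------------------------------------
# Genome and precursor planting
# ---------------------------------------------------------------------------

def generate_genome(config: SyntheticConfig, rng=None) -> dict[str, str]:
    """Uniform-composition random chromosomes (GC ~ 0.5), seed-deterministic."""
    if config.chrom_length <= 0:
        raise ValueError("zero-length chromosome request")
    rng = rng if rng is not None else _rng(config, 0)
    return {
        name: _rand_bases(rng, config.chrom_length)
        for name in chromosome_names(config)
    }


_PAIRS_AT = (("A", "T"), ("T", "A"))
_PAIRS_GC = (("G", "C"), ("C", "G"))
_PAIRS_GU = (("G", "T"), ("T", "G"))


def _sample_pairs(rng, n: int, p_gc: float = 0.5, p_gu: float = 0.0):
    pairs = []
    for _ in range(n):
        u = rng.random()
        if u < p_gu:
            pairs.append(_PAIRS_GU[rng.integers(2)])
        elif u < p_gu + p_gc:
            pairs.append(_PAIRS_GC[rng.integers(2)])
        else:
            pairs.append(_PAIRS_AT[rng.integers(2)])
    return pairs


def _force(pairs, idx_to_type):
    for i, choices in idx_to_type.items():
        pairs[i] = choices
    return pairs


def _assemble(elements, loop: str) -> str:
    left = "".join(e[1] for e in elements)
    right = "".join(e[2] for e in reversed(elements))
    return left + loop + right


def _loop(rng, n: int) -> str:
    return _rand_bases(rng, n, "AC")  # A/C cannot pair with each other


def _ilseq(rng, n: int) -> str:
    return _rand_bases(rng, n, "AC")


def _design_hairpin(cls: str, rng) -> tuple[str, int]:
    """(hairpin sequence, mature offset) for one planted class.

    Classes: "true" (and "c1", which differs only in simulated read
    counts), "c3" 59-nt precursor, "c5" loop-spanning mature, "c6" seven
    star mismatches, "c7" A+U out of range, "c8" hairpin too weak.
    """
    gu_low = rng.integers(2)
    if cls in ("true", "c1"):
        pairs = _force(_sample_pairs(rng, 30, 0.5), {3: _PAIRS_GU[gu_low], 10: _PAIRS_GU[1 - gu_low]})
        return _assemble([("p", l, r) for l, r in pairs], _loop(rng, 6)), 0
    if cls == "c3":
        pairs = _force(_sample_pairs(rng, 27, 0.5), {3: _PAIRS_GU[gu_low], 10: _PAIRS_GU[1 - gu_low]})
        return _assemble([("p", l, r) for l, r in pairs], _loop(rng, 5)), 0
    if cls == "c5":
        pairs = _force(_sample_pairs(rng, 27, 0.6), {20: _PAIRS_GU[gu_low], 24: _PAIRS_GU[1 - gu_low]})
        return _assemble([("p", l, r) for l, r in pairs], _loop(rng, 6)), 19
    if cls == "c6":
        blocks = [5, 4, 3, 2]
        iloops = [2, 2, 3]
        pairs = _force(_sample_pairs(rng, sum(blocks) + 12, 0.7), {1: _PAIRS_GU[gu_low], 3: _PAIRS_GU[1 - gu_low]})
        elements = []
        k = 0
        for bi, blk in enumerate(blocks):
            for _ in range(blk):
                l, r = pairs[k]
                elements.append(("p", l, r))
                k += 1
            if bi < len(iloops):
                n = iloops[bi]
                elements.append(("il", _ilseq(rng, n), _ilseq(rng, n)))
        for _ in range(12):
            l, r = pairs[k]
            elements.append(("p", l, r))
            k += 1
        return _assemble(elements, _loop(rng, 6)), 0
    if cls == "c7":
        pairs = _force(
            _sample_pairs(rng, 31, 0.0),
            {
                5: _PAIRS_GC[rng.integers(2)],
                15: _PAIRS_GC[rng.integers(2)],
                8: _PAIRS_GU[gu_low],
                12: _PAIRS_GU[1 - gu_low],
            },
        )
        return _assemble([("p", l, r) for l, r in pairs], _loop(rng, 6)), 0
    if cls == "c8":
        # all-wobble stem (G:U only, with a rare G:C escape): the hairpin
        # folds but its stacking energy stays above -15 kcal/mol. T runs are
        # capped at two per arm and the locus is insulated with poly-A
        # context, which can pair neither itself nor G, so the marginal stem
        # is still the best structure at its locus.
        pairs: list[tuple[str, str]] = []
        lefts: list[str] = []
        rights: list[str] = []

        def _t_run(arm: list[str]) -> bool:
            return len(arm) >= 2 and arm[-1] == "T" and arm[-2] == "T"

        for _ in range(29):
            ok = [
                c
                for c in _PAIRS_GU
                if not (_t_run(lefts) and c[0] == "T")
                and not (_t_run(rights) and c[1] == "T")
            ]
            l, r = ok[rng.integers(len(ok))] if ok else ("G", "C")
            pairs.append((l, r))
            lefts.append(l)
            rights.append(r)
        return _assemble([("p", l, r) for l, r in pairs], _rand_bases(rng, 6, "CA")), 0
    raise ValueError(f"unknown planted class: {cls}")


def _expected_vector(violated: int | None) -> dict[int, bool]:
    return {k: (k != violated) for k in range(1, 9)}


def _genome_view(genome_ba: dict[str, bytearray]) -> dict[str, str]:
    return {c: ba.decode() for c, ba in genome_ba.items()}


def _count_occurrences(genome: dict[str, str], query: str) -> int:
    return sum(seq.count(query) for seq in genome.values())


def plant_precursors(
    genome: dict[str, str], config: SyntheticConfig, rng=None
) -> tuple[dict[str, str], list[PlantedPrecursor], list[PlantedDecoy], dict[str, list[tuple[int, int]]]]:
    """Write true and decoy hairpins into the genome, verified in place.

    Returns the modified genome, the truth records and the occupied
    genomic intervals (used later to place gene models clear of planted
    loci). Raises when the requested number of loci cannot be placed.
    """
    rng = rng if rng is not None else _rng(config, 1)
    genome_ba = {c: bytearray(s.encode()) for c, s in genome.items()}
    chroms = list(genome_ba)
    scaled, _ = scaled_qtl_intervals(config)
    qtl_by_chrom: dict[str, list[QTLInterval]] = {}
    for iv in scaled:
        qtl_by_chrom.setdefault(iv.chrom, []).append(iv)

    # deterministic slot grid, skipping rescaled QTL intervals
    cursors = {c: 1500 for c in chroms}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def next_slot(chrom: str) -> int:
        pos = cursors[chrom]
        while True:
            span = (pos - 50, pos + FLANK * 2 + 260)
            clash = next(
                (
                    iv
                    for iv in qtl_by_chrom.get(chrom, [])
                    if span[0] <= iv.end + 80 and span[1] >= iv.start - 80
                ),
                None,
            )
            if clash is None:
                break
            pos = clash.end + 200
        if pos + FLANK * 2 + 400 > len(genome_ba[chrom]):
            raise RuntimeError(f"cannot place locus on {chrom}: chromosome full")
        cursors[chrom] = pos + SLOT_STEP
        return pos

    classes = [("true", None)] * config.n_true_precursors + [
        (f"c{k}", k)
        for k in config.decoy_criteria
        for _ in range(config.n_decoys_per_criterion)
    ]
    trues: list[PlantedPrecursor] = []
    decoys: list[PlantedDecoy] = []
    seen_matures: set[str] = set()
    thresholds = CriteriaThresholds()
    for idx, (cls, violated) in enumerate(classes):
        chrom = chroms[idx % len(chroms)]
        slot = next_slot(chrom)
        placed = False
        for _attempt in range(60):
            hairpin, m_off = _design_hairpin(cls, rng)
            flank_alpha = "A" if cls == "c8" else "AC"
            region = (
                _rand_bases(rng, FLANK, flank_alpha)
                + hairpin
                + _rand_bases(rng, FLANK, flank_alpha)
            )
            genome_ba[chrom][slot - 1 : slot - 1 + len(region)] = region.encode()
            view = _genome_view(genome_ba)
            mature = hairpin[m_off : m_off + MATURE_LEN]
            if (
                mature in seen_matures
                or _count_occurrences(view, mature) != 1
                or _count_occurrences(view, revcomp(mature)) != 0
            ):
                continue
            m_start = slot + FLANK + m_off
            m_end = m_start + MATURE_LEN - 1
            tag = SmallRNATag(mature, {"plant": 10})
            cand = evaluate_locus(
                MappedLocus(tag, chrom, m_start, m_end, "+"), view, thresholds
            )
            want = _expected_vector(None if cls == "c1" else violated)
            if cand is not None and cand.criteria == want:
                seen_matures.add(mature)
                h_start, h_end = slot + FLANK, slot + FLANK + len(hairpin) - 1
                if cls == "true":
                    trues.append(
                        PlantedPrecursor(
                            f"mir-synth-{len(trues) + 1:03d}",
                            mature, chrom, h_start, h_end, m_start, m_end,
                        )
                    )
                else:
                    nth = sum(d.violated_criterion == violated for d in decoys) + 1
                    decoys.append(
                        PlantedDecoy(
                            f"decoy-c{violated}-{nth:02d}",
                            mature, chrom, h_start, h_end, m_start, m_end, violated,
                        )
                    )
                occupied[chrom].append((slot - 50, slot + len(region) + 50))
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not verify a {cls} locus after 60 attempts")
    # abundance truth for the true miRNAs
    n_de = round(config.de_fraction * len(trues))
    de_idx = set(rng.choice(len(trues), size=n_de, replace=False).tolist()) if n_de else set()
    known_n = math.floor(config.known_fraction * len(trues))
    known_idx = set(rng.choice(len(trues), size=known_n, replace=False).tolist()) if known_n else set()
    lo, hi = config.planted_log2fc_range
    for i, mir in enumerate(trues):
        mir.base_mean = float(rng.uniform(*config.mean_count_range))
        if i in de_idx:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            mir.planted_log2fc = float(sign * rng.uniform(lo, hi))
        mir.is_known = i in known_idx
    return _genome_view(genome_ba), trues, decoys, occupied


# ---------------------------------------------------------------------------
# Gene models, target embedding, degradome, inventory, reads
# ---------------------------------------------------------------------------

def generate_gene_models(
    genome: dict[str, str],
    config: SyntheticConfig,
    truth: GroundTruth,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
    rng=None,
) -> tuple[dict[str, str], pd.DataFrame, dict[str, str]]:
    """Place gene models inside/outside the rescaled QTL intervals and
    embed true target sites (reverse complements of mature miRNAs) into
    transcripts. Returns (genome, gene table, transcript sequences) and
    fills truth.true_target_pairs / truth.qtl_resident_genes."""
    rng = rng if rng is not None else _rng(config, 2)
    occupied = occupied or {c: [] for c in genome}
    scaled, mapping = scaled_qtl_intervals(config)
    truth.qtl_intervals = scaled
    truth.qtl_scale = mapping
    glen = config.gene_length
    genome_ba = {c: bytearray(s.encode()) for c, s in genome.items()}

    def clashes(chrom: str, s: int, e: int) -> bool:
        return any(s <= oe and e >= os_ for os_, oe in occupied.get(chrom, []))

    rows = []
    n_qtl = math.floor(config.n_genes * config.qtl_fraction)
    # fill QTL intervals round-robin with fully contained genes
    slots_by_iv = []
    for iv in scaled:
        if iv.end - iv.start + 1 < glen:
            continue
        positions = list(range(iv.start, iv.end - glen + 2, glen + 80))
        slots_by_iv.append([(iv.chrom, p) for p in positions])
    placed_qtl = 0
    round_i = 0
    while placed_qtl < n_qtl:
        progressed = False
        for slots in slots_by_iv:
            if placed_qtl >= n_qtl:
                break
            if round_i < len(slots):
                chrom, s = slots[round_i]
                e = s + glen - 1
                if not clashes(chrom, s, e):
                    rows.append((chrom, s, e))
                    placed_qtl += 1
                    progressed = True
        if not progressed:
            raise RuntimeError("QTL intervals too small for requested gene fraction")
        round_i += 1
    # remaining genes clear of QTL intervals and planted loci
    qtl_zones: dict[str, list[tuple[int, int]]] = {}
    for iv in scaled:
        qtl_zones.setdefault(iv.chrom, []).append((iv.start - 80, iv.end + 80))
    cursors = {c: 600 for c in genome}
    chroms = list(genome)
    ci = 0
    while len(rows) < config.n_genes:
        chrom = chroms[ci % len(chroms)]
        ci += 1
        s = cursors[chrom]
        e = s + glen - 1
        cursors[chrom] = s + glen + 80
        if e > len(genome[chrom]) - 400:
            if all(cursors[c] + glen > len(genome[c]) - 400 for c in chroms):
                raise RuntimeError("cannot place requested number of genes")
            continue
        in_qtl = any(s <= ze and e >= zs for zs, ze in qtl_zones.get(chrom, []))
        if in_qtl or clashes(chrom, s - 60, e + 60):
            continue
        rows.append((chrom, s, e))
    genes = pd.DataFrame(
        [
            {
                "gene_id": f"LOC_Syn{i + 1:04d}",
                "chrom": chrom,
                "start": s,
                "end": e,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
            for i, (chrom, s, e) in enumerate(rows)
        ]
    )
    qtl_ids = set()
    for iv in scaled:
        hit = (genes["chrom"] == iv.chrom) & (genes["start"] >= iv.start) & (genes["end"] <= iv.end)
        qtl_ids |= set(genes.loc[hit, "gene_id"])
    truth.qtl_resident_genes = qtl_ids

    # embed one site per (miRNA, gene) pair; one planted site per gene
    available = genes.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    # guarantee at least one QTL-resident target gene in the truth
    if qtl_ids and not available.iloc[0].gene_id in qtl_ids:
        first_qtl = available.index[available.gene_id.isin(qtl_ids)]
        if len(first_qtl):
            k = first_qtl[0]
            order = [k] + [i for i in range(len(available)) if i != k]
            available = available.iloc[order].reset_index(drop=True)
    qtl_first = available
    gi = 0
    for mir in truth.true_mirnas:
        n_sites = 1 + int(config.targets_per_mirna > 1 and rng.random() < 0.5)
        for _ in range(n_sites):
            if gi >= len(qtl_first):
                break
            g = qtl_first.iloc[gi]
            gi += 1
            offset = int(rng.integers(40, glen - 60))
            gs, ge = int(g.start), int(g.end)
            if g.strand == "+":
                seg_start0 = gs - 1 + offset
                genome_ba[g.chrom][seg_start0 : seg_start0 + MATURE_LEN] = revcomp(
                    mir.mature_sequence
                ).encode()
            else:
                seg_start0 = ge - offset - MATURE_LEN
                genome_ba[g.chrom][seg_start0 : seg_start0 + MATURE_LEN] = (
                    mir.mature_sequence.encode()
                )
            n_supp = 1 + int(rng.binomial(config.n_degradome_libraries - 1, 0.4))
            libs = tuple(
                sorted(
                    rng.choice(
                        config.n_degradome_libraries, size=n_supp, replace=False
                    ).tolist()
                )
            )
            truth.true_target_pairs.append(
                TargetPair(mir.name, str(g.gene_id), offset, offset + 12, libs)
            )
    genome = _genome_view(genome_ba)
    transcripts = {}
    for g in genes.itertuples(index=False):
        seg = genome[g.chrom][g.start - 1 : g.end]
        transcripts[f"{g.gene_id}.1"] = seg if g.strand == "+" else revcomp(seg)
    return genome, genes, transcripts


def simulate_tag_counts(
    truth: GroundTruth, config: SyntheticConfig, rng=None
) -> pd.DataFrame:
    """Poisson counts per library for each true miRNA.

    The planted condition effect multiplies the drought mean by
    2^planted_log2fc; control and drought replicates are independent.
    """
    rng = rng if rng is not None else _rng(config, 3)
    libs = config.library_meta
    data = {}
    for mir in truth.true_mirnas:
        row = []
        for lm in libs:
            mean = mir.base_mean * (
                2.0 ** mir.planted_log2fc if lm.condition == "drought" else 1.0
            )
            row.append(int(rng.poisson(mean)))
        data[mir.name] = row
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[lm.library_id for lm in libs]
    )


def simulate_srna_reads(
    truth: GroundTruth,
    config: SyntheticConfig,
    counts: pd.DataFrame | None = None,
    rng=None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Per-library FASTQ records: (id, sequence, quality string).

    Every genuine read is the tag followed by the adapter as a suffix at
    constant high quality; a configurable fraction of low-quality junk
    reads and a few length-violating reads exercise the filters. Decoy
    loci receive fixed counts (2 total reads for the criterion-1 class).
    """
    rng = rng if rng is not None else _rng(config, 4)
    if counts is None:
        counts = simulate_tag_counts(truth, config)
    adapter = config.adapter_sequence
    libs = [lm.library_id for lm in config.library_meta]
    out: dict[str, list[tuple[str, str, str]]] = {lib: [] for lib in libs}

    def emit(lib: str, seq: str, qual_char: str = "I") -> None:
        n = len(out[lib])
        out[lib].append((f"{lib}:read{n + 1}", seq, qual_char * len(seq)))

    for mir in truth.true_mirnas:
        for lib in libs:
            for _ in range(int(counts.loc[mir.name, lib])):
                emit(lib, mir.mature_sequence + adapter)
    for decoy in truth.decoys:
        if decoy.violated_criterion == 1:
            for _ in range(2):
                emit(libs[0], decoy.mature_sequence + adapter)
        else:
            half = config.decoy_read_count // 2
            for lib in libs[:2]:
                for _ in range(half):
                    emit(lib, decoy.mature_sequence + adapter)
    # background tags: random sequences, sparse counts
    for _ in range(config.n_background_tags):
        tag = _rand_bases(rng, int(rng.integers(17, 31)))
        for lib in libs:
            if rng.random() < 0.4:
                for _ in range(int(rng.poisson(2.0)) + 1):
                    emit(lib, tag + adapter)
    for lib in libs:
        n_junk = int(config.low_quality_fraction * len(out[lib]))
        for _ in range(n_junk):
            emit(lib, _rand_bases(rng, MATURE_LEN) + adapter, qual_char="+")
        for _ in range(3):  # too short / too long after trimming
            emit(lib, _rand_bases(rng, 15) + adapter)
            emit(lib, _rand_bases(rng, 31) + adapter)
    return out


def simulate_degradome(
    truth: GroundTruth,
    transcripts: dict[str, str],
    config: SyntheticConfig,
    rng=None,
) -> dict[str, pd.DataFrame]:
    """Degradome tag tables (transcript_id, position, count) per library.

    Each planted pair contributes a 5'-end peak of degradome_peak_height at
    its cleavage position in its supporting libraries; everywhere else a
    uniform low background of single-count tags is laid down, so planted
    peaks are unique maxima (category 0) by construction.
    """
    rng = rng if rng is not None else _rng(config, 5)
    tid_of = {p.gene_id: f"{p.gene_id}.1" for p in truth.true_target_pairs}
    peak_positions: dict[str, set[int]] = {}
    for p in truth.true_target_pairs:
        tid = tid_of[p.gene_id]
        if tid not in transcripts:
            raise ValueError(f"target pair references unknown transcript {tid}")
        if not 1 <= p.cleavage_position <= len(transcripts[tid]):
            raise ValueError("cleavage position outside transcript")
        peak_positions.setdefault(tid, set()).add(p.cleavage_position)
    out = {}
    for li in range(config.n_degradome_libraries):
        lib = f"degradome_{li + 1}"
        rows = []
        for tid in sorted(transcripts):
            L = len(transcripts[tid])
            bg = np.nonzero(rng.random(L) < config.degradome_background_rate)[0] + 1
            for pos in bg:
                if pos not in peak_positions.get(tid, ()):
                    rows.append((tid, int(pos), 1))
        for p in truth.true_target_pairs:
            if li in p.support_libraries:
                rows.append(
                    (tid_of[p.gene_id], p.cleavage_position, config.degradome_peak_height)
                )
        out[lib] = (
            pd.DataFrame(rows, columns=["transcript_id", "position", "count"])
            .sort_values(["transcript_id", "position"])
            .reset_index(drop=True)
        )
    return out


def generate_inventory(gene_ids, fraction: float, seed: int = 0) -> set[str]:
    """Deterministic inventory subset of size floor(fraction * n)."""
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    ids = sorted(gene_ids)
    k = math.floor(fraction * len(ids))
    rng = np.random.default_rng([seed, 6])
    return set(np.array(ids)[rng.choice(len(ids), size=k, replace=False)].tolist()) if k else set()


def generate_dataset(config: SyntheticConfig = SyntheticConfig()) -> SyntheticDataset:
    """Run every generation stage in order; fully determined by the seed."""
    genome = generate_genome(config)
    genome, trues, decoys, occupied = plant_precursors(genome, config)
    truth = GroundTruth(true_mirnas=trues, decoys=decoys)
    genome, genes, transcripts = generate_gene_models(genome, config, truth, occupied)
    counts = simulate_tag_counts(truth, config)
    reads = simulate_srna_reads(truth, config, counts)
    degradome = simulate_degradome(truth, transcripts, config)
    truth.inventory_genes = generate_inventory(
        genes["gene_id"], config.inventory_fraction, config.seed
    )
    reference = {
        f"osa-synth-miR{i + 1:03d}": mir.mature_sequence
        for i, mir in enumerate(truth.true_mirnas)
        if mir.is_known
    }
    return SyntheticDataset(
        config, genome, truth, genes, transcripts, counts, reads, degradome, reference
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> None:
    """Write every pipeline input as plain-text files under outdir."""
    outdir = Path(outdir)
    (outdir / "reads").mkdir(parents=True, exist_ok=True)
    (outdir / "degradome").mkdir(exist_ok=True)
    write_fasta(ds.genome, outdir / "genome.fa")
    write_fasta(ds.transcripts, outdir / "transcripts.fa")
    write_fasta(ds.reference_matures, outdir / "reference_mature.fa")
    write_gff3(ds.genes, outdir / "genes.gff3")
    for lib, reads in ds.reads.items():
        write_fastq(reads, outdir / "reads" / f"{lib}.fastq")
    for lib, df in ds.degradome.items():
        write_tsv(df, outdir / "degradome" / f"{lib}.tsv")
    write_tsv(
        pd.DataFrame({"gene_id": sorted(ds.truth.inventory_genes)}),
        outdir / "inventory.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                {
                    "name": iv.name,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "marker_start": iv.flanking_markers[0],
                    "marker_end": iv.flanking_markers[1],
                }
                for iv in ds.truth.qtl_intervals
            ]
        ),
        outdir / "qtl_intervals.tsv",
    )
    truth = {
        "true_mirnas": [asdict(m) for m in ds.truth.true_mirnas],
        "decoys": [asdict(d) for d in ds.truth.decoys],
        "true_target_pairs": [asdict(p) for p in ds.truth.true_target_pairs],
        "qtl_resident_genes": sorted(ds.truth.qtl_resident_genes),
        "inventory_genes": sorted(ds.truth.inventory_genes),
        "qtl_scale": ds.truth.qtl_scale,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# Promoter alleles for the locus-characterization operations
# ---------------------------------------------------------------------------

PROMOTER_MOTIFS = {"AACA": ("TAACAAACTCCA", 1157), "GARE": ("TCTGTTG", 1145)}


def generate_promoter_alleles(
    seed: int = 0, length: int = 2000, n_snps: int = 2
) -> tuple[str, str, dict]:
    """A synthetic promoter pair with planted cis-motifs and allele SNPs.

    Allele A carries the AACA motif at 1157 and the GARE motif at 1145
    (1-based); allele B differs by exactly n_snps substitutions planted
    outside the motif regions, so the motifs are preserved in both.
    """
    rng = np.random.default_rng([seed, 7])
    seq = list(_rand_bases(rng, length))
    motif_spans = []
    for motif, pos in sorted(PROMOTER_MOTIFS.values(), key=lambda mp: mp[1]):
        seq[pos - 1 : pos - 1 + len(motif)] = list(motif)
        motif_spans.append((pos, pos + len(motif) - 1))
    allele_a = "".join(seq)
    snp_positions: list[int] = []
    b = list(allele_a)
    while len(snp_positions) < n_snps:
        pos = int(rng.integers(1, length + 1))
        if any(s <= pos <= e for s, e in motif_spans) or pos in snp_positions:
            continue
        alt = "ACGT"[int(rng.integers(4))]
        if alt == b[pos - 1]:
            continue
        b[pos - 1] = alt
        snp_positions.append(pos)
    truth = {"snp_positions": sorted(snp_positions), "motifs": dict(PROMOTER_MOTIFS)}
    return allele_a, "".join(b), truth
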