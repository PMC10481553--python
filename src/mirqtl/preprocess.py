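"""Small-RNA read preprocessing: quality filter, adapter trim, length
filter, tag collapsing and exact genome mapping.

Reads enter as single-end FASTQ (Sanger Phred+33). The stage order is
quality -> adapter -> length -> collapse -> map. Filters are conservative
and logged: reads_in == reads_kept + reads_removed at every step.

Mapping is exact full-length string matching on both strands. The precursor
criteria downstream demand an exact sequence match anyway, and synthetic
genomes are desk-scale, so a seeded aligner adds nothing; multi-mapping
tags retain all loci.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

from .util import normalize_seq, revcomp

DEFAULT_MIN_QUALITY = 20.0
DEFAULT_MIN_LEN = 17
DEFAULT_MAX_LEN = 30


@dataclass
class RawRead:
    id: str
    sequence: str
    qualities: list[int]  # per-base Phred scores

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: sequence and quality lengths differ "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities) if self.qualities else 0.0


@dataclass
class SmallRNATag:
    """A collapsed unique read sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class MappedLocus:
    """Exact full-length genomic occurrence of a tag (1-based inclusive)."""

    tag: SmallRNATag
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class FilterLog:
    """Per-stage read conservation accounting."""

    stage: str
    reads_in: int = 0
    reads_kept: int = 0

    @property
    def reads_removed(self) -> int:
        return self.reads_in - self.reads_kept


def read_fastq(path: str | Path, library: str | None = None) -> Iterator[tuple[str, RawRead]]:
    """Yield (library, RawRead) records; library defaults to the file stem."""
    path = Path(path)
    lib = library if library is not None else path.stem
    for rec in SeqIO.parse(str(path), "fastq"):
        yield lib, RawRead(rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])


def quality_filter(
    reads: Iterable[RawRead], min_mean_quality: float = DEFAULT_MIN_QUALITY,
    log: FilterLog | None = None,
) -> list[RawRead]:
    """Retain reads whose mean Phred quality is >= the threshold.

    The cut is on the mean read quality (the common trimmer default
    semantics); a read at exactly the threshold is kept.
    """
    kept = []
    n_in = 0
    for r in reads:
        n_in += 1
        if r.mean_quality >= min_mean_quality:
            kept.append(r)
    if log is not None:
        log.reads_in += n_in
        log.reads_kept += len(kept)
    return kept


def trim_adapter(
    read: RawRead, adapter: str, min_overlap: int = 5
) -> tuple[RawRead, bool]:
    """Remove the longest read suffix that exactly matches an adapter prefix.

    Returns (trimmed read, trimmed flag). A read without a detectable
    adapter suffix (>= min_overlap exact bases) is returned unchanged with
    the flag False.
    """
    if not adapter:
        raise ValueError("empty adapter sequence")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    adapter = normalize_seq(adapter)
    seq = normalize_seq(read.sequence)
    for k in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            cut = len(seq) - k
            return RawRead(read.id, seq[:cut], read.qualities[:cut]), True
    return RawRead(read.id, seq, list(read.qualities)), False


def length_filter(
    items: Iterable, min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN,
    log: FilterLog | None = None,
):
    """Retain reads/tags with min_len <= length <= max_len (inclusive)."""
    kept, n_in = [], 0
    for it in items:
        n_in += 1
        if min_len <= len(it.sequence) <= max_len:
            kept.append(it)
    if log is not None:
        log.reads_in += n_in
        log.reads_kept += len(kept)
    return kept


def collapse_tags(reads_by_library: Mapping[str, Iterable[RawRead]]) -> list[SmallRNATag]:
    """Collapse identical sequences into tags with per-library counts.

    Total reads are conserved: the sum of all tag counts equals the number
    of input reads. Output order is deterministic (by sequence).
    """
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for lib, reads in reads_by_library.items():
        for r in reads:
            counts[normalize_seq(r.sequence)][lib] += 1
    return [SmallRNATag(seq, dict(sorted(libs.items()))) for seq, libs in sorted(counts.items())]


def map_tags(tags: Iterable[SmallRNATag], genome: Mapping[str, str]) -> list[MappedLocus]:
    """All exact full-length occurrences of each tag on both genome strands.

    A minus-strand locus means the reverse complement of the genomic
    substring equals the tag. Coordinates are 1-based inclusive. Tags with
    no hits simply contribute nothing.
    """
    loci: list[MappedLocus] = []
    for tag in tags:
        fwd = tag.sequence
        rev = revcomp(fwd)
        L = len(fwd)
        for chrom in sorted(genome):
            seq = genome[chrom]
            for query, strand in ((fwd, "+"), (rev, "-")):
                start = seq.find(query)
                while start != -1:
                    loci.append(MappedLocus(tag, chrom, start + 1, start + L, strand))
                    start = seq.find(query, start + 1)
    return loci


def preprocess_library(
    reads: Iterable[RawRead],
    adapter: str,
    min_mean_quality: float = DEFAULT_MIN_QUALITY,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_overlap: int = 5,
    logs: dict[str, FilterLog] | None = None,
) -> list[RawRead]:
    """Quality -> adapter -> length for one library; returns clean reads."""
    if logs is None:
        logs = {}
    qlog = logs.setdefault("quality", FilterLog("quality"))
    llog = logs.setdefault("length", FilterLog("length"))
    kept = quality_filter(reads, min_mean_quality, log=qlog)
    trimmed = [trim_adapter(r, adapter, min_overlap)[0] for r in kept]
    return length_filter(trimmed, min_len, max_len, log=llog)


def run_preprocess(
    fastq_by_library: Mapping[str, str | Path],
    genome: Mapping[str, str],
    adapter: str,
    **kwargs,
) -> tuple[list[SmallRNATag], list[MappedLocus], dict[str, dict[str, FilterLog]]]:
    """Full preprocessing over a set of libraries; returns tags and loci."""
    clean: dict[str, list[RawRead]] = {}
    all_logs: dict[str, dict[str, FilterLog]] = {}
    for lib, path in sorted(fastq_by_library.items()):
        logs: dict[str, FilterLog] = {}
        reads = [r for _, r in read_fastq(path, lib)]
        clean[lib] = preprocess_library(reads, adapter, logs=logs, **kwargs)
        all_logs[lib] = logs
    tags = collapse_tags(clean)
    loci = map_tags(tags, genome)
    return tags, loci, all_logs


def write_tag_fasta(tags: Iterable[SmallRNATag], path: str | Path) -> None:
    """Collapsed-tag FASTA in the `>tag<N>_x<count>` convention."""
    with open(path, "w") as fh:
        for n, tag in enumerate(tags, start=1):
            fh.write(f">tag{n}_x{tag.total_count}\n{tag.sequence}\n")


def write_tag_counts(tags: Iterable[SmallRNATag], path: str | Path) -> None:
    tags = list(tags)
    libs = sorted({lib for t in tags for lib in t.counts})
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(libs) + "\n")
        for t in tags:
            fh.write(t.sequence + "\t" + "\t".join(str(t.counts.get(l, 0)) for l in libs) + "\n")
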