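"""Light-weight readers/writers for the formats the pipeline exchanges:
FASTA (via Biopython), the simple gene/mRNA/exon GFF3 subset the generator
emits, and TSV tables (via pandas). Coordinates are 1-based inclusive
throughout, matching GFF3 and the printed QTL marker ranges."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(genes: pd.DataFrame, path: str | Path, source: str = "mirqtl") -> None:
    """Write gene models (one mRNA, one exon per gene) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            base = f"{row.chrom}\t{source}\t%s\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t%s\n"
            fh.write(base % ("gene", f"ID={row.gene_id}"))
            fh.write(base % ("mRNA", f"ID={row.gene_id}.1;Parent={row.gene_id}"))
            fh.write(base % ("exon", f"ID={row.gene_id}.1.exon1;Parent={row.gene_id}.1"))


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Gene-level records from a GFF3 file as a DataFrame.

    Only `gene` features are returned; the ID attribute becomes gene_id.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "gene_id": attrs.get("ID", ""),
                    "chrom": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "strand": parts[6],
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_fastq(
    reads: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    """Write (id, sequence, quality-string) triples as Sanger FASTQ."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
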