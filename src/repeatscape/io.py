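"""Sequence and table I/O conventions.

Coordinates are 0-based half-open everywhere in memory; GFF3 output is
converted to 1-based inclusive on write. FASTA/FASTQ go through
Bio.SeqIO; ``.gz`` paths are handled transparently.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def _open(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def sniff_format(path) -> str:
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def read_seqs(path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ (plain or gzipped) into (id, sequence) tuples."""
    fmt = sniff_format(path)
    with _open(path, "r") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    with _open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def write_fastq(records: Iterable[tuple[str, str]], path, quality: int = 40) -> None:
    """Write (id, seq) records as FASTQ with constant quality (default Q40)."""
    with _open(path, "w") as fh:
        recs = (
            SeqRecord(
                Seq(seq),
                id=name,
                description="",
                letter_annotations={"phred_quality": [quality] * len(seq)},
            )
            for name, seq in records
        )
        SeqIO.write(recs, fh, "fastq")


def write_gff3(features, path) -> None:
    """Write features as GFF3 (input coordinates 0-based half-open).

    ``features`` yields (chrom, source, ftype, start, end, strand, attributes)
    where attributes is an ordered dict.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, source, ftype, start, end, strand, attrs in features:
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                f"{chrom}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attr_str}\n"
            )
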