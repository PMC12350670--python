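"""Readers and writers for the standard formats the pipeline touches."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .filtering import NucRead

_FASTQ_SUFFIXES = {".fastq", ".fq"}
_FASTA_SUFFIXES = {".fasta", ".fa", ".fna"}


def _open_text(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode.rstrip("t"))


def detect_format(path) -> str:
    """``fastq`` or ``fasta`` from the file suffix (gzip-compressed accepted)."""
    path = Path(path)
    suffixes = [s.lower() for s in path.suffixes if s != ".gz"]
    if suffixes and suffixes[-1] in _FASTQ_SUFFIXES:
        return "fastq"
    if suffixes and suffixes[-1] in _FASTA_SUFFIXES:
        return "fasta"
    raise ValueError(f"cannot detect read format from {path.name!r}")


def read_reads(path, fmt: str | None = None) -> Iterator[NucRead]:
    """Iterate merged reads from FASTQ or FASTA (optionally gzipped)."""
    path = Path(path)
    fmt = fmt or detect_format(path)
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, fmt):
            quality = None
            if "phred_quality" in record.letter_annotations:
                quality = "".join(
                    chr(q + 33) for q in record.letter_annotations["phred_quality"]
                )
            yield NucRead(
                read_id=record.id,
                sequence=str(record.seq).upper(),
                quality=quality,
            )


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def write_rejections_tsv(rejections: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\treason\n")
        for read_id, reason in rejections:
            fh.write(f"{read_id}\t{reason}\n")
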