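"""Extraction and translation of VNAR inserts from merged amplicon reads.

The sequencing protocol leaves every VNAR coding insert flanked by two conserved
nucleotide stretches.  A read is kept only when both flanks are found, the bases
strictly between them have a length that is a multiple of three, and the
translation in that anchor-defined frame is free of stop codons and ambiguous
bases.  Counters for each stage are reported so library quality is auditable.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

#: Conserved flank upstream of the VNAR insert in the amplicon design
#: (the single conserved flank of the library construct; the downstream flank
#: is construct-specific and must be supplied in :class:`AnchorConfig`).
FIVE_PRIME_FLANK = "GCCATGGCTGCTCGAGTGGACCAAACACCGCGTGACTGTGAATGGCCCGGGAGGCCA"

_CODON_TABLE = unambiguous_dna_by_id[1]
_FORWARD = dict(_CODON_TABLE.forward_table)
_STOPS = frozenset(_CODON_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_BASES = frozenset("ACGTN")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucRead:
    """A merged nucleotide read (paired-end merging happens upstream)."""

    read_id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if not set(self.sequence) <= _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise ValueError(f"read contains invalid bases: {bad}")


@dataclass(frozen=True)
class AnchorConfig:
    """Conserved-flank configuration for insert extraction.

    ``max_mismatches_per_anchor`` defaults to 0 (exact flank matching);
    ``try_reverse_complement`` retries a failed forward search on the
    reverse-complemented read, so strand orientation does not matter.
    """

    three_prime_anchor: str
    five_prime_anchor: str = FIVE_PRIME_FLANK
    max_mismatches_per_anchor: int = 0
    try_reverse_complement: bool = True

    def __post_init__(self) -> None:
        if not self.five_prime_anchor or not self.three_prime_anchor:
            raise ValueError("anchors must be non-empty")
        if self.max_mismatches_per_anchor < 0:
            raise ValueError("max_mismatches_per_anchor must be >= 0")
        shortest = min(len(self.five_prime_anchor), len(self.three_prime_anchor))
        if self.max_mismatches_per_anchor >= shortest:
            raise ValueError("max_mismatches_per_anchor must be < anchor length")


@dataclass
class FilterStats:
    """Monotone per-stage counters: total >= anchored >= in_frame >= stop_free."""

    total_reads: int = 0
    anchored: int = 0
    in_frame: int = 0
    stop_free_full_length: int = 0

    def as_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "anchored": self.anchored,
            "in_frame": self.in_frame,
            "stop_free_full_length": self.stop_free_full_length,
        }

    def __iter__(self):
        return iter(
            (self.total_reads, self.anchored, self.in_frame, self.stop_free_full_length)
        )


@dataclass
class FilterResult:
    """Output of :func:`filter_full_length`."""

    sequences: list[str] = field(default_factory=list)
    stats: FilterStats = field(default_factory=FilterStats)
    rejections: list[tuple[str, str]] = field(default_factory=list)


def locate_anchor(
    read: "NucRead | str", anchor: str, max_mismatches: int = 0
) -> Optional[tuple[int, int]]:
    """Leftmost span of ``anchor`` in the read within a Hamming mismatch budget.

    Returns a 0-based half-open ``(start, end)`` span or ``None``.  ``N`` bases
    always count as mismatches.  An anchor longer than the read yields ``None``.
    """
    seq = read.sequence if isinstance(read, NucRead) else read
    n, m = len(seq), len(anchor)
    if m == 0 or m > n:
        return None
    if max_mismatches == 0 and "N" not in seq and "N" not in anchor:
        i = seq.find(anchor)
        return (i, i + m) if i >= 0 else None
    a = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(anchor.encode("ascii"), dtype=np.uint8)
    ncode = ord("N")
    windows = np.lib.stride_tricks.sliding_window_view(a, m)
    mismatches = ((windows != b) | (windows == ncode) | (b == ncode)).sum(axis=1)
    hits = np.nonzero(mismatches <= max_mismatches)[0]
    if hits.size == 0:
        return None
    start = int(hits[0])
    return (start, start + m)


def _extract_forward(seq: str, cfg: AnchorConfig) -> Optional[str]:
    five = locate_anchor(seq, cfg.five_prime_anchor, cfg.max_mismatches_per_anchor)
    if five is None:
        return None
    three = locate_anchor(seq, cfg.three_prime_anchor, cfg.max_mismatches_per_anchor)
    if three is None:
        return None
    if three[0] <= five[1]:  # overlapping, out of order, or empty insert
        return None
    return seq[five[1] : three[0]]


def extract_insert(read: "NucRead | str", cfg: AnchorConfig) -> Optional[str]:
    """Bases strictly between the two anchor matches, in coding orientation.

    The forward strand is searched first; if that fails and
    ``cfg.try_reverse_complement`` is set, the reverse complement is searched.
    ``None`` signals a missing anchor, out-of-order anchors, or an empty insert.
    """
    seq = read.sequence if isinstance(read, NucRead) else read
    insert = _extract_forward(seq, cfg)
    if insert is None and cfg.try_reverse_complement:
        insert = _extract_forward(reverse_complement(seq), cfg)
    return insert


def translate_insert(insert: str) -> tuple[Optional[str], Optional[str]]:
    """Translate an insert in the anchor-defined frame.

    Returns ``(protein, None)`` on success or ``(None, reason)`` with reason
    ``"frame"`` (length not a multiple of 3), ``"stop"`` (stop codon anywhere),
    or ``"ambiguous"`` (codon containing N).  Codons are checked left to right,
    so the first offending codon determines the reason.
    """
    if len(insert) % 3 != 0:
        return None, "frame"
    residues = []
    for i in range(0, len(insert), 3):
        codon = insert[i : i + 3]
        if codon in _STOPS:
            return None, "stop"
        aa = _FORWARD.get(codon)
        if aa is None:
            return None, "ambiguous"
        residues.append(aa)
    return "".join(residues), None


def filter_full_length(
    reads: Iterable[NucRead], cfg: AnchorConfig
) -> FilterResult:
    """Apply anchor extraction and translation to every read.

    Output order follows input order of the passing reads.  Rejections record
    ``(read_id, reason)`` with reason one of ``anchor``, ``frame``, ``stop``,
    ``ambiguous``.
    """
    result = FilterResult()
    stats = result.stats
    for read in reads:
        stats.total_reads += 1
        insert = extract_insert(read, cfg)
        if insert is None:
            result.rejections.append((read.read_id, "anchor"))
            continue
        stats.anchored += 1
        if len(insert) % 3 != 0:
            result.rejections.append((read.read_id, "frame"))
            continue
        stats.in_frame += 1
        protein, reason = translate_insert(insert)
        if protein is None:
            result.rejections.append((read.read_id, reason))
            continue
        stats.stop_free_full_length += 1
        result.sequences.append(protein)
    return result


def filter_sequences(
    sequences: Sequence[str], cfg: AnchorConfig, prefix: str = "read"
) -> FilterResult:
    """Convenience wrapper: filter bare nucleotide strings."""
    reads = (NucRead(f"{prefix}{i}", s) for i, s in enumerate(sequences))
    return filter_full_length(reads, cfg)
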