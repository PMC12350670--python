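"""Unique-clone collapsing and repertoire-level statistics.

Reads that survive filtering are collapsed to unique amino-acid sequences and
ranked by prevalence (read count).  On top of that table the module computes the
descriptive statistics used to characterise an immunized library: the
rank-abundance series, singleton and low-count fractions, CDR3 length and
cysteine-count distributions per subtype, per-position CDR3 frequency matrices
(sequence logos), overlap between two libraries, and Pearson correlations of
NGS prevalence against external validation tables (Sanger hit counts, measured
affinities).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .annotation import Annotation, NumberingScheme, DEFAULT_SCHEME, annotate_sequence
from .annotation import RegionDelimitationError
from .filtering import FilterStats

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class UniqueClone:
    """A deduplicated amino-acid VNAR with its prevalence rank within a library."""

    clone_id: str
    aa_sequence: str
    count: int
    rank: int
    library: str
    annotation: Optional[Annotation] = None

    @property
    def cdr3(self) -> Optional[str]:
        return self.annotation.cdr3 if self.annotation else None

    @property
    def subtype(self) -> Optional[str]:
        return self.annotation.subtype.subtype if self.annotation else None


@dataclass
class RepertoireDataset:
    """All unique clones of one library plus the filter counters they came from."""

    library: str
    clones: list[UniqueClone] = field(default_factory=list)
    filter_stats: Optional[FilterStats] = None
    unannotated: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def total_reads(self) -> int:
        return sum(c.count for c in self.clones)

    def annotated_clones(self) -> list[UniqueClone]:
        return [c for c in self.clones if c.annotation is not None]

    def annotate(self, scheme: NumberingScheme = DEFAULT_SCHEME) -> dict[str, int]:
        """Annotate every clone in place; returns rejection-reason counts.

        Clones that cannot be delimited are kept (as unannotated) but excluded
        from subtype/CDR3 statistics.
        """
        reasons: Counter = Counter()
        for clone in self.clones:
            try:
                clone.annotation = annotate_sequence(clone.aa_sequence, scheme)
            except RegionDelimitationError as exc:
                clone.annotation = None
                reasons[exc.reason] += 1
        self.unannotated = dict(reasons)
        return self.unannotated

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clones:
            rows.append(
                {
                    "clone_id": c.clone_id,
                    "library": c.library,
                    "count": c.count,
                    "rank": c.rank,
                    "subtype": c.subtype or "",
                    "cdr3": c.cdr3 or "",
                    "sequence": c.aa_sequence,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["clone_id", "library", "count", "rank", "subtype", "cdr3", "sequence"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, library: Optional[str] = None) -> "RepertoireDataset":
        df = pd.read_csv(path, sep="\t", dtype={"cdr3": str, "subtype": str})
        lib = library or (str(df["library"].iloc[0]) if len(df) else "library")
        ds = cls(library=lib)
        for _, row in df.iterrows():
            ds.clones.append(
                UniqueClone(
                    clone_id=str(row["clone_id"]),
                    aa_sequence=str(row["sequence"]),
                    count=int(row["count"]),
                    rank=int(row["rank"]),
                    library=lib,
                )
            )
        return ds


def collapse_unique(
    aa_sequences: Iterable[str],
    library: str,
    filter_stats: Optional[FilterStats] = None,
) -> RepertoireDataset:
    """Collapse translated reads into ranked unique clones.

    Rank is by descending count with lexicographic tie-break on the sequence;
    clone ids are ``"<library>:<rank>"``.
    """
    counts = Counter(aa_sequences)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    clones = [
        UniqueClone(
            clone_id=f"{library}:{rank}",
            aa_sequence=seq,
            count=count,
            rank=rank,
            library=library,
        )
        for rank, (seq, count) in enumerate(ordered, start=1)
    ]
    return RepertoireDataset(library=library, clones=clones, filter_stats=filter_stats)


@dataclass(frozen=True)
class AbundanceFractions:
    """Fractions of unique clones below count thresholds (and singletons)."""

    singleton_fraction: float
    below: dict[int, float]
    n_clones: int


def abundance_fractions(
    ds: RepertoireDataset, thresholds: Sequence[int] = (10,)
) -> AbundanceFractions:
    """Fraction of unique clones with count < each threshold, plus singletons."""
    if not ds.clones:
        raise ValueError("empty_dataset")
    counts = np.array([c.count for c in ds.clones])
    n = counts.size
    below = {int(t): float((counts < t).sum() / n) for t in thresholds}
    return AbundanceFractions(
        singleton_fraction=float((counts == 1).sum() / n), below=below, n_clones=n
    )


def rank_abundance_series(ds: RepertoireDataset) -> list[tuple[int, int]]:
    """Ordered (rank, count) pairs; counts are non-increasing in rank."""
    return [(c.rank, c.count) for c in sorted(ds.clones, key=lambda c: c.rank)]


@dataclass(frozen=True)
class LengthSummary:
    """Five-number box summary with 1.5*IQR whiskers (linear-interpolated quartiles)."""

    n: int
    mean: float
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["outliers"] = list(self.outliers)
        return d


def _summarize(values: np.ndarray) -> LengthSummary:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    fence_low, fence_high = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= fence_low) & (values <= fence_high)]
    outliers = tuple(
        np.sort(values[(values < fence_low) | (values > fence_high)]).tolist()
    )
    return LengthSummary(
        n=int(values.size),
        mean=float(values.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


def length_distribution(
    ds: RepertoireDataset, region: str = "cdr3", by_subtype: bool = False
):
    """Box-plot summary of region lengths over annotated clones.

    Whiskers extend to the most extreme observation within 1.5*IQR of the
    quartiles; observations beyond are listed as outliers.  With
    ``by_subtype`` a dict of per-subtype summaries is returned.
    """
    clones = ds.annotated_clones()
    if not clones:
        raise ValueError("no annotated clones")

    def region_length(c: UniqueClone) -> int:
        lo, hi = c.annotation.region_map.span(region)
        return hi - lo

    if not by_subtype:
        return _summarize(np.array([region_length(c) for c in clones]))
    groups: dict[str, list[int]] = {}
    for c in clones:
        groups.setdefault(c.subtype, []).append(region_length(c))
    return {sub: _summarize(np.array(v)) for sub, v in sorted(groups.items())}


def cysteine_distribution(
    ds: RepertoireDataset, scope: str = "full", by_subtype: bool = False
):
    """Histogram of cysteine counts over annotated clones.

    ``scope`` is ``"full"`` (whole sequence) or ``"cdr3"``.  The histogram
    values sum to the number of annotated clones.
    """
    if scope not in ("full", "cdr3"):
        raise ValueError(f"unknown scope {scope!r}")
    clones = ds.annotated_clones()

    def n_cys(c: UniqueClone) -> int:
        if scope == "full":
            return c.aa_sequence.count("C")
        return c.cdr3.count("C")

    if not by_subtype:
        return dict(Counter(n_cys(c) for c in clones))
    groups: dict[str, Counter] = {}
    for c in clones:
        groups.setdefault(c.subtype, Counter())[n_cys(c)] += 1
    return {sub: dict(cnt) for sub, cnt in sorted(groups.items())}


def build_logo(cdr3_set: Sequence[str]) -> pd.DataFrame:
    """Position frequency matrix of equal-length sequences.

    Rows are positions, columns the 20 amino acids; each row sums to 1.
    Mixed lengths raise ``ValueError("length_mismatch")``.
    """
    seqs = list(cdr3_set)
    if not seqs:
        raise ValueError("empty input")
    length = len(seqs[0])
    if length < 1 or any(len(s) != length for s in seqs):
        raise ValueError("length_mismatch")
    matrix = np.zeros((length, len(AA_ALPHABET)))
    index = {aa: j for j, aa in enumerate(AA_ALPHABET)}
    for s in seqs:
        for i, ch in enumerate(s):
            matrix[i, index[ch]] += 1
    matrix /= len(seqs)
    return pd.DataFrame(matrix, columns=list(AA_ALPHABET))


@dataclass(frozen=True)
class OverlapResult:
    """Sequence-level overlap between two libraries."""

    unique_to_a: int
    shared: int
    unique_to_b: int
    shared_fraction: float


def dataset_overlap(a: RepertoireDataset, b: RepertoireDataset) -> OverlapResult:
    """Overlap of full-length amino-acid sequences; shared_fraction is over the union."""
    set_a = {c.aa_sequence for c in a.clones}
    set_b = {c.aa_sequence for c in b.clones}
    shared = len(set_a & set_b)
    union = len(set_a | set_b)
    return OverlapResult(
        unique_to_a=len(set_a) - shared,
        shared=shared,
        unique_to_b=len(set_b) - shared,
        shared_fraction=shared / union if union else 0.0,
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    n: int


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with its square."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length_mismatch")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate")
    r = float(sstats.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, r_squared=r * r, n=int(x.size))


@dataclass(frozen=True)
class AffinityRecord:
    """Measured dissociation constant for one clone (consumed, never computed)."""

    clone_id: str
    kd: float  # molar

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError("kd must be > 0")


def prevalence_affinity_correlation(
    ds: RepertoireDataset,
    affinities: Iterable[AffinityRecord],
    transform: str = "raw",
) -> CorrelationResult:
    """Correlate NGS clone counts against measured affinities.

    ``transform`` is ``"raw"`` (counts vs KD, mirroring a linear plot) or
    ``"log10_kd"`` (counts vs log10 KD, for log-scale affinity spreads).
    Requires >= 3 clone ids present in both inputs.
    """
    if transform not in ("raw", "log10_kd"):
        raise ValueError(f"unknown transform {transform!r}")
    by_id = {c.clone_id: c.count for c in ds.clones}
    matched = [(by_id[a.clone_id], a.kd) for a in affinities if a.clone_id in by_id]
    if len(matched) < 3:
        raise ValueError("need >= 3 matched clone ids")
    counts = [m[0] for m in matched]
    kds = [math.log10(m[1]) if transform == "log10_kd" else m[1] for m in matched]
    return pearson_r2(counts, kds)
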