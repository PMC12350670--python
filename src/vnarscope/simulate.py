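"""Synthetic paired VNAR repertoires with full ground truth.

The generator emulates what deep sequencing of an immunized phage-display
library looks like: a heavy-tailed (Zipf) clonotype abundance spectrum in which
~90% of unique sequences are singletons, a shared background repertoire between
two libraries plus clonally expanded clonotypes private to each, the VNAR
domain architecture with canonical and subtype-defining non-canonical
cysteines, CDR3 lengths concentrated on 5-25 residues with a rare ultralong
tail (>80 aa), conserved nucleotide flanks around every insert, and
frameshift/stop-codon contamination of the read stream.

Every read carries a provenance record and every clonotype a truth record
(centroid, region spans, subtype, per-library counts), so the filtering,
annotation, collapsing and discovery stages can be verified exactly.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .annotation import RegionMap
from .filtering import AnchorConfig, FilterStats, NucRead, reverse_complement

# ---------------------------------------------------------------------------
# Domain scaffold: fixed framework blocks shared by every simulated clonotype.
# Landmarks agree with the default NumberingScheme: canonical Cys1 at index 21,
# canonical Cys2 at index 80, CDR3 from 81, FR4 motif "WGQGT".
# ---------------------------------------------------------------------------
_FR1 = "ARVDQTPQTITKETGESLTINC"  # 22 aa, canonical Cys1 at 21
_FR2_PREFIX = "TYWYRKNPGS"  # 10 aa at [30, 40)
_FR2_SUFFIX = "GRYVE"  # 5 aa at [48, 53)
_FR3_SUFFIX = "SGSKSFSLRIKDLTVADSATYIC"  # 23 aa at [58, 81), Cys2 at 80
_FR4 = "WGQGTAVTVN"  # 10 aa
_FR4_TYPE_I = "WGQGTCVTVN"  # FR4 with the type-I non-canonical cysteine
_CDR1_LEN = 8
_HV2_LEN = 8
_HV4_LEN = 5
_FR4_MOTIF = "WGQGT"

_ALPHABET = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_NO_CYS = np.frombuffer(b"ADEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_NO_CYS_NO_TRP = np.frombuffer(b"ADEFGHIKLMNPQRSTVY", dtype=np.uint8)

#: Fixed reverse-translation table (one codon per amino acid) so nucleotide
#: deduplication coincides with amino-acid deduplication.
CODON_TABLE = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

#: Conserved flank placed downstream of every simulated insert (SfiI-style
#: cassette boundary, mirroring how inserts are excised from the phagemid).
THREE_PRIME_FLANK = "GGCCTCGGGGGCCGCACATCACCATCACCATTAA"


def default_anchor_config() -> AnchorConfig:
    from .filtering import FIVE_PRIME_FLANK

    return AnchorConfig(
        five_prime_anchor=FIVE_PRIME_FLANK,
        three_prime_anchor=THREE_PRIME_FLANK,
        max_mismatches_per_anchor=0,
        try_reverse_complement=True,
    )


def _default_cdr3_length_weights() -> dict[int, float]:
    """Triangular mass on 5-25 aa peaked at 14, plus a tiny ultralong tail."""
    weights = {length: 11.0 - abs(length - 14) * 0.45 for length in range(5, 26)}
    for length in range(81, 86):
        weights[length] = 0.02
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of one simulated library pair.

    ``n_reads`` is per library.  ``abundance_exponent`` is the Zipf exponent of
    the background clonotype spectrum; ``specific_mass`` is the read fraction
    allocated to the clonally expanded, library-private clonotypes.  Each read
    of a clonotype independently acquires substitutions at per-position rate
    ``mutation_rate`` (multiplied inside CDR3); unmutated reads stack on the
    centroid, mutated reads scatter into mostly-unique variants, which is what
    makes a strong abundance head coexist with a ~90% singleton tail.
    Contamination channels are mutually exclusive per read; sequencing errors
    are substitution-only and ride on top.
    """

    seed: int = 0
    n_reads: int = 50_000
    background_clonotypes: int = 25_000
    specific_clonotypes: int = 4
    specific_mass: float = 0.15
    abundance_exponent: float = 1.05
    specific_cdr3_length: Optional[int] = 14
    subtype_mixture: tuple = (("I", 0.12), ("II", 0.60), ("III", 0.08), ("IV", 0.20))
    mutation_rate: float = 0.002
    cdr3_mutation_multiplier: float = 10.0
    frameshift_rate: float = 0.05
    stop_codon_rate: float = 0.02
    sequencing_error_rate: float = 0.001
    library_names: tuple[str, str] = ("target", "control")
    cdr3_length_weights: Optional[tuple] = None  # ((length, weight), ...)

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        for name in ("specific_mass", "mutation_rate", "frameshift_rate",
                     "stop_codon_rate", "sequencing_error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(w for _, w in self.subtype_mixture) - 1.0) > 1e-9:
            raise ValueError("subtype_mixture must sum to 1")
        if self.frameshift_rate + self.stop_codon_rate > 1:
            raise ValueError("contamination rates must sum to <= 1")

    def length_weights(self) -> dict[int, float]:
        if self.cdr3_length_weights is not None:
            return dict(self.cdr3_length_weights)
        return _default_cdr3_length_weights()

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["subtype_mixture"] = dict(self.subtype_mixture)
        d["cdr3_length_weights"] = (
            dict(self.cdr3_length_weights) if self.cdr3_length_weights else None
        )
        return d


def discovery_benchmark_params(seed: int = 0) -> SimulationParams:
    """A scaled-down library pair for exercising clade discovery.

    Four expanded target-private clonotypes at CDR3 length 14 over a shared
    Zipf background, sized so each planted clonotype diversifies into well
    over 30 unique CDR3 variants.
    """
    return SimulationParams(
        seed=seed,
        n_reads=20_000,
        background_clonotypes=3_000,
        specific_clonotypes=4,
        specific_mass=0.30,
        specific_cdr3_length=14,
        sequencing_error_rate=0.0,
        frameshift_rate=0.0,
        stop_codon_rate=0.0,
    )


# ---------------------------------------------------------------------------
# Scaffold construction
# ---------------------------------------------------------------------------


@dataclass
class ClonotypeTruth:
    """Planted truth for one clonotype centroid."""

    clonotype_id: str
    centroid_aa: str
    cdr3: str
    subtype: str
    specific: bool
    library: Optional[str]  # None = shared background
    region_map: RegionMap
    counts: dict[str, int] = field(default_factory=dict)  # planted reads per library


def _rand_letters(rng: np.random.Generator, n: int, alphabet: np.ndarray) -> list[str]:
    return [chr(c) for c in rng.choice(alphabet, size=n)]


def generate_scaffold(
    rng: np.random.Generator, subtype: str, cdr3_length: int
) -> tuple[str, RegionMap]:
    """Build one VNAR amino-acid scaffold with the cysteine layout of ``subtype``.

    Variable blocks (CDR1, HV2, HV4, CDR3) are drawn cysteine-free and the
    subtype-defining cysteines are planted explicitly, so the planted subtype
    label is exact.  CDR3 draws are rejected while they contain the FR4 motif,
    which keeps region delimitation unambiguous.
    """
    cdr1 = _rand_letters(rng, _CDR1_LEN, _NO_CYS)
    hv2 = _rand_letters(rng, _HV2_LEN, _NO_CYS)
    hv4 = _rand_letters(rng, _HV4_LEN, _NO_CYS)
    while True:
        cdr3 = _rand_letters(rng, cdr3_length, _NO_CYS)
        if _FR4_MOTIF not in "".join(cdr3):
            break
    fr4 = _FR4

    if subtype == "I":
        hv2[int(rng.integers(_HV2_LEN))] = "C"
        fr4 = _FR4_TYPE_I
        pos = rng.choice(cdr3_length, size=2, replace=False)
        for p in pos:
            cdr3[int(p)] = "C"
    elif subtype in ("II", "III"):
        j = int(rng.integers(1, _CDR1_LEN - 1))
        cdr1[j] = "C"
        if subtype == "III":
            cdr1[j + 1] = "W"
        else:
            # keep the conserved-context motif absent: no W next to the cysteine
            for k in (j - 1, j + 1):
                if cdr1[k] == "W":
                    cdr1[k] = chr(int(rng.choice(_NO_CYS_NO_TRP)))
        cdr3[int(rng.integers(cdr3_length))] = "C"
    elif subtype != "IV":
        raise ValueError(f"unknown subtype {subtype!r}")

    aa = (
        _FR1
        + "".join(cdr1)
        + _FR2_PREFIX
        + "".join(hv2)
        + _FR2_SUFFIX
        + "".join(hv4)
        + _FR3_SUFFIX
        + "".join(cdr3)
        + fr4
    )
    cdr3_start = len(_FR1) + _CDR1_LEN + len(_FR2_PREFIX) + _HV2_LEN + len(
        _FR2_SUFFIX
    ) + _HV4_LEN + len(_FR3_SUFFIX)
    region_map = RegionMap(
        fr1=(0, 22),
        cdr1=(22, 30),
        fr2_hv2=(30, 53),
        hv4_fr3=(53, cdr3_start),
        cdr3=(cdr3_start, cdr3_start + cdr3_length),
        fr4=(cdr3_start + cdr3_length, len(aa)),
        length=len(aa),
        canonical_cys=(21, cdr3_start - 1),
    )
    return aa, region_map


# ---------------------------------------------------------------------------
# Clonotype planting and diversification
# ---------------------------------------------------------------------------


@dataclass
class ReadProvenance:
    read_id: str
    channel: str  # clean / frameshift / stop
    n_errors: int  # sequencing-error substitutions on top of the channel
    variant_aa: str
    clonotype_id: str


@dataclass
class LibraryTruth:
    library: str
    variant_counts: dict[str, int] = field(default_factory=dict)  # planted, pre-channel
    clean_counts: dict[str, int] = field(default_factory=dict)  # realized clean reads
    variant_clonotype: dict[str, str] = field(default_factory=dict)
    provenance: list[ReadProvenance] = field(default_factory=list)
    channel_counts: Counter = field(default_factory=Counter)

    def expected_filter_stats(self) -> FilterStats:
        """Predicted filter counters; exact when sequencing_error_rate == 0."""
        total = sum(self.channel_counts.values())
        frameshift = self.channel_counts.get("frameshift", 0)
        stop = self.channel_counts.get("stop", 0)
        return FilterStats(
            total_reads=total,
            anchored=total,
            in_frame=total - frameshift,
            stop_free_full_length=total - frameshift - stop,
        )


@dataclass
class SyntheticTruth:
    """Everything planted: clonotypes, per-library variants, per-read provenance."""

    clonotypes: list[ClonotypeTruth]
    libraries: dict[str, LibraryTruth]

    def clonotype_by_id(self, clonotype_id: str) -> ClonotypeTruth:
        return next(c for c in self.clonotypes if c.clonotype_id == clonotype_id)

    def cdr3_to_clonotypes(self, library: str) -> dict[str, set[str]]:
        """Map each emitted variant CDR3 string to the clonotype ids producing it."""
        spans = {
            c.clonotype_id: c.region_map.cdr3 for c in self.clonotypes
        }
        out: dict[str, set[str]] = {}
        lt = self.libraries[library]
        for aa, cid in lt.variant_clonotype.items():
            lo, hi = spans[cid]
            out.setdefault(aa[lo:hi], set()).add(cid)
        return out

    def specific_clonotypes(self, library: str) -> list[ClonotypeTruth]:
        return [c for c in self.clonotypes if c.specific and c.library == library]


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def _diversify(
    rng: np.random.Generator,
    clonotype: ClonotypeTruth,
    count: int,
    params: SimulationParams,
) -> Counter:
    """Variant multiset (aa -> planted count) for one clonotype in one library.

    Each of the ``count`` reads independently acquires per-position
    substitutions (CDR3-enriched).  Reads with no substitution remain the
    centroid, so the centroid keeps the bulk of an expanded clonotype's mass
    while the mutated reads scatter into mostly-singleton variants.
    """
    centroid = clonotype.centroid_aa
    if params.mutation_rate == 0:
        return Counter({centroid: count})
    length = len(centroid)
    p = np.full(length, params.mutation_rate)
    lo, hi = clonotype.region_map.cdr3
    p[lo:hi] *= params.cdr3_mutation_multiplier

    mask = rng.random((count, length)) < p
    mutated_rows = np.nonzero(mask.any(axis=1))[0]
    variants: Counter = Counter()
    variants[centroid] += count - mutated_rows.size
    base = np.frombuffer(centroid.encode("ascii"), dtype=np.uint8)
    for row in mutated_rows:
        mutated = base.copy()
        for pos in np.nonzero(mask[row])[0]:
            choices = _ALPHABET[_ALPHABET != mutated[pos]]
            mutated[pos] = rng.choice(choices)
        variants[mutated.tobytes().decode("ascii")] += 1
    if variants[centroid] == 0:
        del variants[centroid]
    return variants


def plant_clonotypes(
    params: SimulationParams, rng: np.random.Generator
) -> SyntheticTruth:
    """Draw centroids, assign Zipf counts per library, diversify into variants.

    Background clonotypes are shared between the two libraries (independently
    sampled counts); expanded specific clonotypes are private to their library.
    """
    subtype_names = [s for s, _ in params.subtype_mixture]
    subtype_probs = np.array([w for _, w in params.subtype_mixture])
    lengths_dist = params.length_weights()
    length_values = np.array(sorted(lengths_dist))
    length_probs = np.array([lengths_dist[v] for v in length_values])
    length_probs = length_probs / length_probs.sum()

    def draw_clonotype(cid: str, specific: bool, library: Optional[str]) -> ClonotypeTruth:
        subtype = subtype_names[int(rng.choice(len(subtype_names), p=subtype_probs))]
        if specific and params.specific_cdr3_length is not None:
            cdr3_len = params.specific_cdr3_length
        else:
            cdr3_len = int(rng.choice(length_values, p=length_probs))
        aa, region_map = generate_scaffold(rng, subtype, cdr3_len)
        return ClonotypeTruth(
            clonotype_id=cid,
            centroid_aa=aa,
            cdr3=aa[region_map.cdr3[0] : region_map.cdr3[1]],
            subtype=subtype,
            specific=specific,
            library=library,
            region_map=region_map,
        )

    background = [
        draw_clonotype(f"bg{k}", specific=False, library=None)
        for k in range(params.background_clonotypes)
    ]
    specific = {
        lib: [
            draw_clonotype(f"{lib}_sp{k}", specific=True, library=lib)
            for k in range(params.specific_clonotypes)
        ]
        for lib in params.library_names
    }

    bg_weights = _zipf_weights(params.background_clonotypes, params.abundance_exponent)
    bg_weights = bg_weights * (1.0 - params.specific_mass)
    n_spec = params.specific_clonotypes
    if n_spec > 0:
        # expanded clonotypes share the specific mass equally, so each is
        # guaranteed a comparable pool of diversified members
        sp_weights = np.full(n_spec, params.specific_mass / n_spec)
    else:
        sp_weights = np.zeros(0)
        bg_weights = bg_weights / bg_weights.sum()

    truth = SyntheticTruth(
        clonotypes=background
        + [c for lib in params.library_names for c in specific[lib]],
        libraries={},
    )

    for lib in params.library_names:
        clonotypes = specific[lib] + background
        weights = np.concatenate([sp_weights, bg_weights])
        weights = weights / weights.sum()
        counts = rng.multinomial(params.n_reads, weights)
        lt = LibraryTruth(library=lib)
        for clonotype, count in zip(clonotypes, counts):
            count = int(count)
            clonotype.counts[lib] = count
            if count == 0:
                continue
            for aa, n in _diversify(rng, clonotype, count, params).items():
                lt.variant_counts[aa] = lt.variant_counts.get(aa, 0) + n
                lt.variant_clonotype.setdefault(aa, clonotype.clonotype_id)
        truth.libraries[lib] = lt
    return truth


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def _reverse_translate(aa: str) -> str:
    return "".join(CODON_TABLE[ch] for ch in aa)


def emit_reads(
    truth: SyntheticTruth,
    params: SimulationParams,
    rng: np.random.Generator,
    anchors: Optional[AnchorConfig] = None,
) -> dict[str, list[NucRead]]:
    """Reverse-translate variants, wrap with anchors, inject contamination.

    Each read is assigned one channel: ``frameshift`` (one-base deletion inside
    the insert), ``stop`` (one codon replaced by TAA), or ``clean``; sequencing
    errors (substitutions over the whole read) ride on top at their own rate.
    Strand is random per read.  Read order is shuffled.  With
    ``sequencing_error_rate == 0`` the filter counters and the clean clone
    table are exactly predictable from the truth records.
    """
    anchors = anchors or default_anchor_config()
    five, three = anchors.five_prime_anchor, anchors.three_prime_anchor
    reads_by_library: dict[str, list[NucRead]] = {}
    for lib in params.library_names:
        lt = truth.libraries[lib]
        entries = []  # (sequence, channel, n_errors, variant_aa)
        for aa in sorted(lt.variant_counts):
            count = lt.variant_counts[aa]
            insert = _reverse_translate(aa)
            for _ in range(count):
                u = rng.random()
                if u < params.frameshift_rate:
                    channel = "frameshift"
                    pos = int(rng.integers(len(insert)))
                    read_insert = insert[:pos] + insert[pos + 1 :]
                elif u < params.frameshift_rate + params.stop_codon_rate:
                    channel = "stop"
                    codon = int(rng.integers(len(insert) // 3))
                    read_insert = (
                        insert[: 3 * codon] + "TAA" + insert[3 * codon + 3 :]
                    )
                else:
                    channel = "clean"
                    read_insert = insert
                seq = five + read_insert + three
                n_errors = int(rng.binomial(len(seq), params.sequencing_error_rate))
                if n_errors:
                    arr = list(seq)
                    for pos in rng.choice(len(seq), size=n_errors, replace=False):
                        current = arr[pos]
                        options = [b for b in _BASES if b != current]
                        arr[pos] = options[int(rng.integers(3))]
                    seq = "".join(arr)
                if rng.random() < 0.5:
                    seq = reverse_complement(seq)
                entries.append((seq, channel, n_errors, aa))

        order = rng.permutation(len(entries))
        reads = []
        for i, idx in enumerate(order):
            seq, channel, n_errors, aa = entries[idx]
            read_id = f"{lib}:r{i:06d}"
            reads.append(NucRead(read_id=read_id, sequence=seq, quality="I" * len(seq)))
            lt.provenance.append(
                ReadProvenance(
                    read_id=read_id,
                    channel=channel,
                    n_errors=n_errors,
                    variant_aa=aa,
                    clonotype_id=lt.variant_clonotype[aa],
                )
            )
            lt.channel_counts[channel] += 1
            if channel == "clean" and n_errors == 0:
                lt.clean_counts[aa] = lt.clean_counts.get(aa, 0) + 1
        reads_by_library[lib] = reads
    return reads_by_library


@dataclass
class SimulationResult:
    """Reads plus truth for one simulated library pair."""

    params: SimulationParams
    truth: SyntheticTruth
    reads: dict[str, list[NucRead]]
    anchors: AnchorConfig

    def write(self, outdir) -> None:
        """Write per-library FASTQ (gzip), truth tables (TSV) and a params echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for lib, reads in self.reads.items():
            # mtime=0 keeps repeated writes byte-identical
            with open(outdir / f"{lib}.fastq.gz", "wb") as raw:
                with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as fh:
                    for r in reads:
                        fh.write(
                            f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n".encode()
                        )
        with open(outdir / "clonotypes.tsv", "w") as fh:
            fh.write(
                "clonotype_id\tsubtype\tspecific\tlibrary\tcdr3\t"
                + "\t".join(f"count_{lib}" for lib in self.params.library_names)
                + "\tcentroid\n"
            )
            for c in self.truth.clonotypes:
                counts = "\t".join(
                    str(c.counts.get(lib, 0)) for lib in self.params.library_names
                )
                fh.write(
                    f"{c.clonotype_id}\t{c.subtype}\t{int(c.specific)}\t"
                    f"{c.library or 'shared'}\t{c.cdr3}\t{counts}\t{c.centroid_aa}\n"
                )
        for lib, lt in self.truth.libraries.items():
            with open(outdir / f"{lib}.provenance.tsv", "w") as fh:
                fh.write("read_id\tchannel\tn_errors\tclonotype_id\n")
                for p in lt.provenance:
                    fh.write(
                        f"{p.read_id}\t{p.channel}\t{p.n_errors}\t{p.clonotype_id}\n"
                    )
        with open(outdir / "params.json", "w") as fh:
            json.dump(self.params.as_dict(), fh, indent=2, default=str)


def simulate(params: SimulationParams) -> SimulationResult:
    """Run the full generator: plant clonotypes, diversify, emit reads."""
    rng = np.random.default_rng(params.seed)
    anchors = default_anchor_config()
    truth = plant_clonotypes(params, rng)
    reads = emit_reads(truth, params, rng, anchors)
    return SimulationResult(params=params, truth=truth, reads=reads, anchors=anchors)
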