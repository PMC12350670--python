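"""VNAR region delimitation and cysteine-based subtype classification.

A VNAR domain is laid out FR1 - CDR1 - FR2/HV2 - HV4/FR3 - CDR3 - FR4.  Unlike
conventional V domains it lacks CDR2; two hypervariable loops (HV2, HV4) sit in
the frameworks instead.  All immunoglobulin folds carry two canonical
disulfide-forming cysteines (in FR1 and at the end of FR3, immediately before
CDR3); VNAR subtypes are defined by the positioning of *additional*,
non-canonical cysteines:

* Type I   - extra cysteines in FR2 and FR4 paired with an even number of
  cysteines in CDR3, clamping CDR3 against HV2;
* Type II  - a single extra cysteine in CDR1 pairing with CDR3, a probing loop;
* Type III - like type II but with conserved CDR1 sequence context (here: a
  tryptophan adjacent to the CDR1 cysteine);
* Type IV  - only the two canonical cysteines, the most flexible fold.

Because no universal residue-numbering table exists for VNARs, regions are
delimited by rules anchored on the two canonical cysteines and a conserved
tryptophan-containing FR4 motif; every rule is exposed in
:class:`NumberingScheme` and shared with the synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

REGION_NAMES = ("fr1", "cdr1", "fr2_hv2", "hv4_fr3", "cdr3", "fr4")

SUBTYPES = ("I", "II", "III", "IV", "other")


class RegionDelimitationError(ValueError):
    """Raised when a sequence cannot be delimited; ``reason`` is machine-readable."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class NumberingScheme:
    """Rule set locating VNAR regions relative to conserved landmarks.

    Windows are absolute 0-based half-open index ranges on the amino-acid
    sequence; the first cysteine inside each window is taken as canonical.
    CDR1 is placed relative to canonical Cys1, the HV4/FR3 block ends at
    canonical Cys2, CDR3 runs from just after Cys2 to the first FR4 motif.
    """

    cys1_window: tuple[int, int] = (15, 28)
    cys2_window: tuple[int, int] = (70, 90)
    cdr1_offsets: tuple[int, int] = (1, 9)
    hv4_fr3_length: int = 28
    cdr3_start_offset: int = 1
    fr4_start_motif: str = "WGQGT"
    min_length: int = 80
    max_length: int = 200

    def as_dict(self) -> dict:
        return {
            "cys1_window": list(self.cys1_window),
            "cys2_window": list(self.cys2_window),
            "cdr1_offsets": list(self.cdr1_offsets),
            "hv4_fr3_length": self.hv4_fr3_length,
            "cdr3_start_offset": self.cdr3_start_offset,
            "fr4_start_motif": self.fr4_start_motif,
            "min_length": self.min_length,
            "max_length": self.max_length,
        }


DEFAULT_SCHEME = NumberingScheme()


@dataclass(frozen=True)
class RegionMap:
    """Per-region 0-based half-open spans within one amino-acid sequence.

    The six regions partition ``[0, length)``; ``canonical_cys`` holds the
    indices of the two canonical cysteines (in FR1 and at the end of HV4/FR3).
    """

    fr1: tuple[int, int]
    cdr1: tuple[int, int]
    fr2_hv2: tuple[int, int]
    hv4_fr3: tuple[int, int]
    cdr3: tuple[int, int]
    fr4: tuple[int, int]
    length: int
    canonical_cys: tuple[int, int]

    def span(self, region: str) -> tuple[int, int]:
        return getattr(self, region)

    def spans(self) -> dict[str, tuple[int, int]]:
        return {name: getattr(self, name) for name in REGION_NAMES}

    def region_of(self, index: int) -> Optional[str]:
        for name in REGION_NAMES:
            lo, hi = getattr(self, name)
            if lo <= index < hi:
                return name
        return None

    @property
    def cdr3_length(self) -> int:
        return self.cdr3[1] - self.cdr3[0]


def delimit_regions(aa: str, scheme: NumberingScheme = DEFAULT_SCHEME) -> RegionMap:
    """Delimit the six VNAR regions of ``aa`` or raise :class:`RegionDelimitationError`.

    Rejection reasons: ``length`` (outside configured bounds),
    ``no_canonical_cys`` (either canonical cysteine absent from its window),
    ``no_fr4_motif`` (FR4 motif missing downstream of Cys2, or CDR3 empty),
    ``region_geometry`` (rules produced inverted/overlapping spans).
    """
    n = len(aa)
    if not scheme.min_length <= n <= scheme.max_length:
        raise RegionDelimitationError("length", f"{n} outside configured bounds")

    def first_cys(window: tuple[int, int]) -> Optional[int]:
        lo, hi = max(window[0], 0), min(window[1], n)
        pos = aa.find("C", lo, hi)
        return pos if pos >= 0 else None

    cys1 = first_cys(scheme.cys1_window)
    cys2 = first_cys(scheme.cys2_window)
    if cys1 is None or cys2 is None or cys2 <= cys1:
        raise RegionDelimitationError("no_canonical_cys")

    cdr1 = (cys1 + scheme.cdr1_offsets[0], cys1 + scheme.cdr1_offsets[1])
    hv4_start = cys2 + 1 - scheme.hv4_fr3_length
    cdr3_start = cys2 + scheme.cdr3_start_offset
    fr4_pos = aa.find(scheme.fr4_start_motif, cdr3_start)
    if fr4_pos < 0 or fr4_pos == cdr3_start:
        raise RegionDelimitationError("no_fr4_motif")

    spans = (
        (0, cdr1[0]),
        cdr1,
        (cdr1[1], hv4_start),
        (hv4_start, cdr3_start),
        (cdr3_start, fr4_pos),
        (fr4_pos, n),
    )
    boundaries = [0, cdr1[0], cdr1[1], hv4_start, cdr3_start, fr4_pos, n]
    if any(b > a for a, b in zip(boundaries[1:], boundaries[:-1])) or cys1 >= cdr1[0]:
        raise RegionDelimitationError("region_geometry")

    return RegionMap(*spans, length=n, canonical_cys=(cys1, cys2))


def extract_cdr3(aa: str, scheme: NumberingScheme = DEFAULT_SCHEME) -> str:
    """CDR3 substring of ``aa``; propagates delimitation rejections."""
    rm = delimit_regions(aa, scheme)
    return aa[rm.cdr3[0] : rm.cdr3[1]]


def count_cysteines(aa: str, region_map: RegionMap) -> dict[str, int]:
    """Cysteine counts per region plus ``total`` over the whole sequence."""
    counts = {}
    for name in REGION_NAMES:
        lo, hi = region_map.span(name)
        counts[name] = aa.count("C", lo, hi)
    counts["total"] = aa.count("C")
    return counts


@dataclass(frozen=True)
class SubtypeCall:
    """A subtype assignment with its supporting non-canonical cysteine layout."""

    subtype: str
    extra_cys_by_region: dict = field(default_factory=dict)
    rationale: str = ""


def classify_subtype(
    aa: str, region_map: RegionMap, scheme: NumberingScheme = DEFAULT_SCHEME
) -> SubtypeCall:
    """Classify a delimited VNAR into subtype I/II/III/IV/other.

    Rules are applied with precedence IV -> I -> III -> II -> other over the
    non-canonical cysteines (every C except the two canonical positions):

    * IV    - no non-canonical cysteines at all;
    * I     - >=1 in FR2/HV2 and >=1 in FR4 and an even count >=2 in CDR3;
    * III   - exactly 1 in CDR1 and >=1 in CDR3, with a tryptophan adjacent
      to the CDR1 cysteine (the conserved CDR1 context);
    * II    - exactly 1 in CDR1 and >=1 in CDR3 (context absent);
    * other - any remaining layout.
    """
    canonical = set(region_map.canonical_cys)
    extra = [i for i, ch in enumerate(aa) if ch == "C" and i not in canonical]
    by_region: dict[str, int] = {name: 0 for name in REGION_NAMES}
    for i in extra:
        region = region_map.region_of(i)
        if region is not None:
            by_region[region] += 1

    cdr1_c, fr2_c = by_region["cdr1"], by_region["fr2_hv2"]
    cdr3_c, fr4_c = by_region["cdr3"], by_region["fr4"]

    if not extra:
        return SubtypeCall("IV", by_region, "canonical cysteines only")
    if fr2_c >= 1 and fr4_c >= 1 and cdr3_c >= 2 and cdr3_c % 2 == 0:
        return SubtypeCall(
            "I", by_region, "FR2+FR4 cysteines paired with even CDR3 cysteines"
        )
    if cdr1_c == 1 and cdr3_c >= 1:
        lo, hi = region_map.cdr1
        cys_pos = aa.index("C", lo, hi)
        neighbors = aa[max(cys_pos - 1, 0) : cys_pos] + aa[cys_pos + 1 : cys_pos + 2]
        if "W" in neighbors:
            return SubtypeCall(
                "III", by_region, "CDR1 cysteine with conserved adjacent tryptophan"
            )
        return SubtypeCall("II", by_region, "CDR1 cysteine pairing with CDR3")
    return SubtypeCall("other", by_region, "non-canonical cysteine layout unmatched")


@dataclass(frozen=True)
class Annotation:
    """Bundle attached to a clone once delimitation succeeds."""

    region_map: RegionMap
    subtype: SubtypeCall
    cdr3: str


def annotate_sequence(
    aa: str, scheme: NumberingScheme = DEFAULT_SCHEME
) -> Annotation:
    """Delimit, extract CDR3 and classify in one step (raises on rejection)."""
    rm = delimit_regions(aa, scheme)
    call = classify_subtype(aa, rm, scheme)
    return Annotation(region_map=rm, subtype=call, cdr3=aa[rm.cdr3[0] : rm.cdr3[1]])
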