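"""Chromosome band arithmetic and an approximate band <-> coordinate map.

Cytogenetic regions (``q14q33``, ``p12``, whole arms, whole chromosomes)
are compared symbolically: two band intervals on the same chromosome arm
overlap iff their numeric band ranges intersect. Band numbers are ordered
the way the nomenclature orders them along the arm, centromere to
telomere: ``q11 < q14 < q21 < q33``, sub-bands nest (``q13.1`` lies
inside ``q13``).

For array-CGH segments, which arrive as genomic coordinates, a band map
is required. No curated cytoband table is bundled; instead this module
generates an APPROXIMATE map from per-chromosome lengths, centromere
positions and terminal band numbers (GRCh37 scale), interpolating
linearly in band-number space. It is adequate for matching coarse CGH
segments to karyotype bands and for simulating cgh.tsv files (the
simulator uses the same map, so round trips are self-consistent), but it
is NOT a substitute for a real cytoband annotation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "BandRegion",
    "parse_band",
    "parse_band_interval",
    "band_to_coords",
    "coords_to_region",
    "CHROM_LENGTHS",
]

# Approximate GRCh37 chromosome lengths (bp), centromere positions (bp)
# and terminal band numbers per arm. Linear interpolation only.
CHROM_LENGTHS = {
    "1": 249_250_000, "2": 243_200_000, "3": 198_020_000, "4": 191_150_000,
    "5": 180_900_000, "6": 171_100_000, "7": 159_140_000, "8": 146_360_000,
    "9": 141_210_000, "10": 135_530_000, "11": 135_000_000, "12": 133_850_000,
    "13": 115_170_000, "14": 107_350_000, "15": 102_530_000, "16": 90_350_000,
    "17": 81_200_000, "18": 78_080_000, "19": 59_130_000, "20": 63_030_000,
    "21": 48_130_000, "22": 51_300_000, "X": 155_270_000, "Y": 59_370_000,
}

_CENTROMERES = {
    "1": 125_000_000, "2": 93_300_000, "3": 91_000_000, "4": 50_400_000,
    "5": 48_400_000, "6": 61_000_000, "7": 59_900_000, "8": 45_600_000,
    "9": 49_000_000, "10": 40_200_000, "11": 53_700_000, "12": 35_800_000,
    "13": 17_900_000, "14": 17_600_000, "15": 19_000_000, "16": 36_600_000,
    "17": 24_000_000, "18": 17_200_000, "19": 26_500_000, "20": 27_500_000,
    "21": 13_200_000, "22": 14_700_000, "X": 60_600_000, "Y": 12_500_000,
}

# Terminal band value per arm (band-number scale, see _band_value).
_TERMINAL = {
    "1": (3.633, 4.4), "2": (2.53, 3.73), "3": (2.63, 2.9),
    "4": (1.63, 3.52), "5": (1.533, 3.53), "6": (2.53, 2.7),
    "7": (2.23, 3.63), "8": (2.33, 2.43), "9": (2.43, 3.43),
    "10": (1.53, 2.63), "11": (1.55, 2.5), "12": (1.333, 2.433),
    "13": (1.3, 3.4), "14": (1.3, 3.233), "15": (1.3, 2.63),
    "16": (1.33, 2.43), "17": (1.33, 2.53), "18": (1.132, 2.3),
    "19": (1.33, 1.343), "20": (1.3, 1.333), "21": (1.3, 2.23),
    "22": (1.3, 1.333), "X": (2.233, 2.8), "Y": (1.132, 1.2),
}

_BAND_RE = re.compile(r"^([pq])(\d{1,2})(?:\.(\d+))?$")


def _band_value(band: str) -> Tuple[str, float]:
    """Map a band name to (arm, ordinal value). 'q14' -> ('q', 1.4);
    'q13.32' -> ('q', 1.332). 'qter'/'pter' map to +inf on their arm;
    bare 'p'/'q' denote the whole arm start (value 0)."""
    band = band.strip()
    if band in ("pter", "qter"):
        return band[0], math.inf
    m = _BAND_RE.match(band)
    if not m:
        raise ValueError(f"unparseable band designation: {band!r}")
    arm, digits, sub = m.groups()
    value = int(digits) / 10.0
    if sub:
        value += int(sub) / 10.0 ** (len(sub) + 1)
    return arm, value


@dataclass(frozen=True)
class BandRegion:
    """A contiguous cytogenetic region on one chromosome.

    ``arm`` is 'p', 'q' or '*' (whole chromosome). ``lo``/``hi`` are
    band ordinal values (lo <= hi); hi = inf means 'to the telomere'.
    A single band b is the degenerate interval [b, b + width(b)) so that
    q22 overlaps q22.1.
    """

    arm: str
    lo: float
    hi: float

    WHOLE: "BandRegion" = None  # set below

    def overlaps(self, other: "BandRegion") -> bool:
        if self.arm == "*" or other.arm == "*":
            return True
        if self.arm != other.arm:
            return False
        return self.lo <= other.hi and other.lo <= self.hi

    def contains_band(self, band: str) -> bool:
        return self.overlaps(parse_band(band))

    def __str__(self) -> str:
        if self.arm == "*":
            return "whole"
        hi = "ter" if math.isinf(self.hi) else f"{self.hi:g}"
        return f"{self.arm}[{self.lo:g},{hi}]"


BandRegion.WHOLE = BandRegion("*", 0.0, math.inf)


def _single_band_region(band: str) -> BandRegion:
    arm, v = _band_value(band)
    if math.isinf(v):
        return BandRegion(arm, v, v)
    # pad to the resolution of the stated band so sub-bands are contained
    s = band.replace(".", "")[1:]
    width = 10.0 ** -(len(s) - 1)
    return BandRegion(arm, v, v + width * 0.999)


def parse_band(band: str) -> BandRegion:
    """Region covered by a single band designation (e.g. 'q22', 'p13.1')."""
    return _single_band_region(band)


def parse_band_interval(text: str) -> BandRegion:
    """Region for an ISCN band spec: 'q14q33', 'q21', 'p12p13', 'q35qter'.

    Whole-arm specs 'p'/'q' (e.g. from i(8)(q10)) are handled by the
    caller passing e.g. 'q10qter'.
    """
    text = text.strip()
    parts = re.findall(r"[pq](?:ter|\d{1,2}(?:\.\d+)?)", text)
    if not parts or "".join(parts) != text:
        raise ValueError(f"unparseable band interval: {text!r}")
    if len(parts) == 1:
        return _single_band_region(parts[0])
    if len(parts) != 2:
        raise ValueError(f"band interval has >2 endpoints: {text!r}")
    a = _single_band_region(parts[0])
    b = _single_band_region(parts[1])
    if a.arm != b.arm:
        # spans the centromere; treat conservatively as whole chromosome
        return BandRegion.WHOLE
    return BandRegion(a.arm, min(a.lo, b.lo), max(a.hi, b.hi))


def _arm_bounds(chrom: str, arm: str) -> Tuple[int, int, float]:
    """(coord at centromere end, coord at telomere end, terminal value)."""
    length = CHROM_LENGTHS[chrom]
    cen = _CENTROMERES[chrom]
    p_max, q_max = _TERMINAL[chrom]
    if arm == "p":
        return cen, 0, p_max
    return cen, length, q_max


def band_to_coords(chrom: str, region: BandRegion) -> Tuple[int, int]:
    """Approximate genomic interval (0-based half-open) for a region."""
    chrom = chrom.lstrip("chr") if chrom.startswith("chr") else chrom
    if region.arm == "*":
        return 0, CHROM_LENGTHS[chrom]
    cen_end, tel_end, vmax = _arm_bounds(chrom, region.arm)
    lo_f = min(region.lo / vmax, 1.0)
    hi_f = min(region.hi / vmax, 1.0) if not math.isinf(region.hi) else 1.0
    a = round(cen_end + (tel_end - cen_end) * lo_f)
    b = round(cen_end + (tel_end - cen_end) * hi_f)
    return (min(a, b), max(a, b))


def coords_to_region(chrom: str, start: int, end: int) -> Optional[BandRegion]:
    """Approximate band region for a genomic interval on one chromosome."""
    chrom = chrom[3:] if chrom.startswith("chr") else chrom
    if chrom not in CHROM_LENGTHS:
        return None
    cen = _CENTROMERES[chrom]
    length = CHROM_LENGTHS[chrom]
    p_max, q_max = _TERMINAL[chrom]
    if end <= cen:  # entirely on p
        lo = (cen - end) / cen * p_max
        hi = (cen - start) / cen * p_max
        return BandRegion("p", lo, hi)
    if start >= cen:  # entirely on q
        lo = (start - cen) / (length - cen) * q_max
        hi = (end - cen) / (length - cen) * q_max
        return BandRegion("q", lo, hi)
    return BandRegion.WHOLE  # spans the centromere


# Loci of the leukemia panel genes used for CNV/SNV overlap detection
# (chromosome, band). Standard genome-annotation knowledge.
GENE_LOCI = {
    "ASXL1": ("20", "q11.21"),
    "BCOR": ("X", "p11.4"),
    "DNMT3A": ("2", "p23.3"),
    "IDH1": ("2", "q34"),
    "IDH2": ("15", "q26.1"),
    "JAK2": ("9", "p24.1"),
    "KRAS": ("12", "p12.1"),
    "NF1": ("17", "q11.2"),
    "NRAS": ("1", "p13.2"),
    "PTPN11": ("12", "q24.13"),
    "RUNX1": ("21", "q22.12"),
    "SF3B1": ("2", "q33.1"),
    "SRSF2": ("17", "q25.1"),
    "STAG2": ("X", "q25"),
    "TET2": ("4", "q24"),
    "TP53": ("17", "p13.1"),
    "U2AF1": ("21", "q22.3"),
    "WT1": ("11", "p13"),
}
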