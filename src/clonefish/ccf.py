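"""Cancer cell fraction (CCF) estimation from single evidence modalities.

Each diagnostic modality yields its own route to the fraction of
analyzed cells carrying an aberration:

* panel sequencing VAFs: CCF = 2*VAF for an autosomal heterozygous
  variant (CCF = VAF on a hemizygous locus),
* metaphase karyotyping / interphase FISH: a direct cell proportion
  with a Wilson binomial interval,
* array-CGH: inversion of the log2 fluorescence ratio under a
  one-copy-change-in-diploid-background model.

Estimates above 1 are capped and flagged rather than silently rescaled;
no purity/ploidy correction is attempted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import FrozenSet, Optional

from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CcfSource", "CopyContext", "CcfEstimate",
    "ccf_from_vaf", "ccf_from_counts", "ccf_from_log2ratio",
    "FLAG_CAPPED", "FLAG_HEMIZYGOUS", "FLAG_AMBIGUOUS",
]

FLAG_CAPPED = "capped_at_1"
FLAG_HEMIZYGOUS = "hemizygous_assumed"
FLAG_AMBIGUOUS = "ambiguous"

# Half-width of the fallback uncertainty band when no read counts are
# available for a VAF (clinical reports often state VAF only).
DEFAULT_VAF_BAND = 0.05


class CcfSource(str, enum.Enum):
    VAF = "vaf"
    METAPHASE = "metaphase"
    FISH = "fish"
    CGH = "cgh"
    OVERLAP_MODEL = "overlap_model"


class CopyContext(str, enum.Enum):
    AUTOSOMAL_HET = "autosomal_het"
    HEMIZYGOUS = "hemizygous"


@dataclass(frozen=True)
class CcfEstimate:
    """A cancer cell fraction in [0, 1] with uncertainty and provenance."""

    ccf: float
    ci_low: float
    ci_high: float
    source: CcfSource
    flags: FrozenSet[str] = frozenset()
    aberration_id: Optional[str] = None
    timepoint_index: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.ccf <= self.ci_high <= 1.0):
            raise ValueError(
                f"CCF interval out of order: "
                f"[{self.ci_low}, {self.ccf}, {self.ci_high}]")

    def with_identity(self, aberration_id: str, timepoint_index: int
                      ) -> "CcfEstimate":
        return CcfEstimate(self.ccf, self.ci_low, self.ci_high, self.source,
                           self.flags, aberration_id, timepoint_index)

    @property
    def se(self) -> float:
        """Gaussian-equivalent standard error from the 95% interval."""
        return max((self.ci_high - self.ci_low) / 3.92, 5e-3)


def _clip01(x: float) -> float:
    return min(1.0, max(0.0, x))


def ccf_from_vaf(vaf: float,
                 copy_context: CopyContext = CopyContext.AUTOSOMAL_HET,
                 depth: Optional[int] = None,
                 alt_reads: Optional[int] = None) -> CcfEstimate:
    """CCF from a variant allele frequency.

    Autosomal heterozygous: CCF = min(1, 2*VAF) (flag ``capped_at_1``
    when 2*VAF > 1). Hemizygous (X/Y in males): CCF = VAF, flagged
    ``hemizygous_assumed``. Uncertainty is a Wilson interval on
    alt_reads/depth scaled by the same factor when read counts are
    available, else a fixed +-0.05 band.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF {vaf} outside [0, 1]")
    factor = 1.0 if copy_context == CopyContext.HEMIZYGOUS else 2.0
    flags = set()
    if copy_context == CopyContext.HEMIZYGOUS:
        flags.add(FLAG_HEMIZYGOUS)
    raw = factor * vaf
    ccf = raw
    if raw > 1.0:
        ccf = 1.0
        flags.add(FLAG_CAPPED)
    if depth and alt_reads is not None:
        lo, hi = proportion_confint(alt_reads, depth, method="wilson")
    else:
        lo, hi = vaf - DEFAULT_VAF_BAND, vaf + DEFAULT_VAF_BAND
    ci_low = _clip01(factor * lo)
    ci_high = _clip01(factor * hi)
    return CcfEstimate(ccf=ccf, ci_low=min(ci_low, ccf),
                       ci_high=max(ci_high, ccf), source=CcfSource.VAF,
                       flags=frozenset(flags))


def ccf_from_counts(with_count: int, total: int,
                    source: CcfSource = CcfSource.METAPHASE) -> CcfEstimate:
    """CCF as a cell proportion with a 95% Wilson binomial interval."""
    if total <= 0:
        raise ValueError("total count must be positive")
    if not 0 <= with_count <= total:
        raise ValueError("count out of range")
    ccf = with_count / total
    lo, hi = proportion_confint(with_count, total, alpha=0.05, method="wilson")
    return CcfEstimate(ccf=ccf, ci_low=min(float(lo), ccf),
                       ci_high=max(float(hi), ccf), source=source)


def ccf_from_log2ratio(log2_ratio: float, direction: str,
                       noise_sd: float = 0.05) -> CcfEstimate:
    """CCF from an array-CGH log2 ratio, one-copy change in a diploid
    background.

    Forward model for a cell fraction f: ratio = (2-f)/2 for a loss,
    (2+f)/2 for a gain; inverted here as f = 2 - 2**(r+1) (loss) and
    f = 2**(r+1) - 2 (gain). Results outside [0, 1] are clipped and
    flagged. ``noise_sd`` (log2 units) propagates into the interval.
    """
    direction = getattr(direction, "value", direction)
    if direction == "loss":
        if log2_ratio > 0:
            raise ValueError("loss requires log2_ratio <= 0")
        f = 2.0 - 2.0 ** (log2_ratio + 1.0)
        lo = 2.0 - 2.0 ** (log2_ratio + 1.96 * noise_sd + 1.0)
        hi = 2.0 - 2.0 ** (log2_ratio - 1.96 * noise_sd + 1.0)
    elif direction == "gain":
        if log2_ratio < 0:
            raise ValueError("gain requires log2_ratio >= 0")
        f = 2.0 ** (log2_ratio + 1.0) - 2.0
        lo = 2.0 ** (log2_ratio - 1.96 * noise_sd + 1.0) - 2.0
        hi = 2.0 ** (log2_ratio + 1.96 * noise_sd + 1.0) - 2.0
    else:
        raise ValueError(f"unknown CNV direction {direction!r}")
    flags = set()
    if not 0.0 <= f <= 1.0:
        flags.add(FLAG_CAPPED)
    ccf = _clip01(f)
    return CcfEstimate(ccf=ccf, ci_low=min(_clip01(lo), ccf),
                       ci_high=max(_clip01(hi), ccf), source=CcfSource.CGH,
                       flags=frozenset(flags))
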