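"""Scenario engine for an SNV/indel whose locus is covered by a CNV.

When a copy-number event overlaps the position of a point mutation, the
naive heterozygous rule CCF = 2*VAF breaks down. The analyzed cell
population is split into four classes by which events each cell carries:

    w  cells with both the CNV and the SNV/indel
    x  cells with the CNV only
    y  cells with the SNV/indel only
    z  cells with neither

with w + x + y + z = 1 and the copy-number clone size CCF_CNV = w + x
known from karyotype/FISH/CGH. The measured allele frequency is

    VAF = (cnv_value*w + y) / (1*w + 1*x + 2*y + 2*z)   CNV = deletion
    VAF = (cnv_value*w + y) / (3*w + 3*x + 2*y + 2*z)   CNV = duplication

where ``cnv_value`` counts mutant copies in the doubly-affected cells.
Three orderings of the two events are possible:

    scenario 1  CNV first, then SNV in the same cells  (y = 0, cnv_value 1)
    scenario 2  SNV first, then CNV in the same cells  (x = 0; cnv_value
                0 or 1 for a deletion, 1 or 2 for a duplication,
                depending on which allele the CNV hits)
    scenario 3  independent cell populations           (w = 0, cnv_value 1)

Scenario 2's two allele assignments make four cases in total. Each case
is solved in closed form for (w, x, y, z) and the mutation's cell
fraction CCF_SNV = w + y; cases whose fractions leave [0, 1] (beyond a
tolerance eps) are excluded -- infeasibility is data, not an error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import List, Tuple

from .ccf import FLAG_AMBIGUOUS, FLAG_CAPPED, CcfEstimate, CcfSource

__all__ = [
    "CnvType", "OverlapCase", "predict_vaf", "enumerate_overlap_cases",
    "resolve_overlap", "NoFeasibleCaseError", "DEFAULT_EPS",
]

DEFAULT_EPS = 0.05


class CnvType(str, enum.Enum):
    DELETION = "deletion"
    DUPLICATION = "duplication"


class NoFeasibleCaseError(ValueError):
    """All four overlap cases violate w+x+y+z=1; inputs are inconsistent
    at the given tolerance -- review eps or the CCF_CNV estimate."""


@dataclass(frozen=True)
class OverlapCase:
    """One solved scenario/cnv_value configuration."""

    scenario: int            # 1, 2 or 3
    cnv_value: int           # mutant copies in w-cells: 0, 1 or 2
    cnv_type: CnvType
    w: float
    x: float
    y: float
    z: float
    ccf_cnv: float           # input: w + x
    vaf: float               # input
    ccf_snv: float           # output: w + y (clipped to [0,1] if noisy)
    feasible: bool
    violation: float         # largest constraint breach; 0 when feasible

    @property
    def label(self) -> str:
        return f"scenario{self.scenario}/cnv_value={self.cnv_value}"


def _total_copies(cnv_type: CnvType) -> int:
    # copies at the locus inside CNV cells: deletion -> 1, duplication -> 3
    return 1 if cnv_type == CnvType.DELETION else 3


def predict_vaf(case: OverlapCase) -> float:
    """Allele frequency implied by a case's cell fractions (forward model)."""
    w, x, y, z = case.w, case.x, case.y, case.z
    if abs(w + x + y + z - 1.0) > 1e-9:
        raise ValueError("cell fractions must sum to 1")
    n = _total_copies(case.cnv_type)
    denom = n * w + n * x + 2.0 * y + 2.0 * z
    if denom == 0.0:
        raise ValueError("no copies present: denominator is zero")
    return (case.cnv_value * w + y) / denom


def _mk_case(scenario: int, cnv_value: int, cnv_type: CnvType,
             w: float, x: float, y: float, z: float,
             vaf: float, ccf_cnv: float, eps: float) -> OverlapCase:
    violation = max(0.0, *(-v for v in (w, x, y, z)),
                    *(v - 1.0 for v in (w, x, y, z)))
    feasible = violation <= eps
    # a variant never observed in any read is treated as absent: the
    # deleted-allele case (cnv_value = 0) would otherwise ascribe it the
    # whole CNV clone as invisible mutation history
    ccf_snv = w + y if vaf > 0.0 else 0.0
    if feasible:
        ccf_snv = min(1.0, max(0.0, ccf_snv))
    return OverlapCase(scenario=scenario, cnv_value=cnv_value,
                       cnv_type=cnv_type, w=w, x=x, y=y, z=z,
                       ccf_cnv=ccf_cnv, vaf=vaf, ccf_snv=ccf_snv,
                       feasible=feasible, violation=violation)


def enumerate_overlap_cases(vaf: float, ccf_cnv: float, cnv_type: CnvType,
                            eps: float = DEFAULT_EPS) -> List[OverlapCase]:
    """Solve all four cases in closed form.

    The denominator of the VAF equation is constant once ccf_cnv is
    fixed: D = 2 - ccf_cnv for a deletion, 2 + ccf_cnv for a
    duplication, because CNV cells contribute 1 (resp. 3) copies and all
    other cells 2. Each case then solves linearly for its single free
    fraction. Returned order: scenario 1; scenario 2 with its two
    cnv_values (ascending); scenario 3.
    """
    if not 0.0 <= vaf <= 1.0 or not 0.0 <= ccf_cnv <= 1.0:
        raise ValueError("vaf and ccf_cnv must lie in [0, 1]")
    cnv_type = CnvType(cnv_type)
    C = ccf_cnv
    n = _total_copies(cnv_type)
    D = n * C + 2.0 * (1.0 - C)

    cases: List[OverlapCase] = []

    # scenario 1: CNV first (y = 0, cnv_value = 1, w free)
    w = vaf * D
    cases.append(_mk_case(1, 1, cnv_type, w, C - w, 0.0, 1.0 - C,
                          vaf, C, eps))

    # scenario 2: SNV first (x = 0, w = ccf_cnv, y free)
    cvs = (0, 1) if cnv_type == CnvType.DELETION else (1, 2)
    for cv in cvs:
        y = vaf * D - cv * C
        cases.append(_mk_case(2, cv, cnv_type, C, 0.0, y, 1.0 - C - y,
                              vaf, C, eps))

    # scenario 3: independent populations (w = 0, x = ccf_cnv, y free)
    y = vaf * D
    cases.append(_mk_case(3, 1, cnv_type, 0.0, C, y, 1.0 - C - y,
                          vaf, C, eps))
    return cases


def resolve_overlap(vaf: float, ccf_cnv: float, cnv_type: CnvType,
                    eps: float = DEFAULT_EPS
                    ) -> Tuple[List[CcfEstimate], List[OverlapCase]]:
    """CCF estimate(s) for a CNV-covered variant.

    Returns (estimates, surviving_cases). A single surviving case yields
    one unflagged estimate; several yield one estimate each, flagged
    ``ambiguous`` (downstream reconstruction branches per case, never
    auto-selects). With ccf_cnv = 0 the CNV is absent and the
    heterozygous rule applies: one estimate, CCF = 2*VAF.

    Raises :class:`NoFeasibleCaseError` when no case survives at eps.
    """
    if ccf_cnv == 0.0:
        est = _estimate_from(min(1.0, 2.0 * vaf), 2.0 * vaf, ambiguous=False)
        return [est], []
    cases = enumerate_overlap_cases(vaf, ccf_cnv, cnv_type, eps)
    survivors = [c for c in cases if c.feasible]
    if not survivors:
        best = min(c.violation for c in cases)
        raise NoFeasibleCaseError(
            f"no overlap case satisfies w+x+y+z=1 at eps={eps} "
            f"(smallest violation {best:.4f}); review eps or the inputs")
    ambiguous = len(survivors) > 1
    estimates = [_estimate_from(c.ccf_snv, c.w + c.y, ambiguous)
                 for c in survivors]
    return estimates, survivors


def _estimate_from(ccf: float, raw: float, ambiguous: bool) -> CcfEstimate:
    flags = set()
    if raw > 1.0:
        flags.add(FLAG_CAPPED)
    if ambiguous:
        flags.add(FLAG_AMBIGUOUS)
    ccf = min(1.0, max(0.0, ccf))
    band = 0.05
    return CcfEstimate(ccf=ccf, ci_low=max(0.0, ccf - band),
                       ci_high=min(1.0, ccf + band),
                       source=CcfSource.OVERLAP_MODEL, flags=frozenset(flags))
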