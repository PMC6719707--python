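"""Trophic-level standardization of biota monitoring data.

Monitoring programs sample different species at different trophic
levels; comparability against a biota quality standard (EQS_biota,
usually set for fish around TL 4 in fresh waters, TL 5 in marine
systems) is achieved by adjusting each measurement to the reference TL
and a reference tissue composition:

    C_adj = C_meas × TMF^(target_TL − TL(x)) × f_ref / f_sample

with f_ref = 0.05 (standard lipid content) or 0.26 (standard dry-weight
content) and f_sample the monitored organism's own lipid or dry-weight
fraction.  The same TMF power law translates an EQS between TLs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

#: Standard lipid content used for normalized reporting (fraction).
REFERENCE_LIPID_FRACTION = 0.05
#: Standard dry-weight content used for normalized reporting (fraction).
REFERENCE_DRY_FRACTION = 0.26

#: Default reference TLs by system type.
FRESHWATER_TARGET_TL = 4.0
MARINE_TARGET_TL = 5.0


class AdjustmentMode(str, enum.Enum):
    lipid = "lipid"
    dry_weight = "dry_weight"


class ComplianceVerdict(str, enum.Enum):
    compliant = "compliant"
    non_compliant = "non_compliant"
    indeterminate = "indeterminate"


@dataclass(frozen=True)
class AdjustmentResult:
    c_meas: float  # µg/kg ww
    tl_x: float
    tmf_applied: float
    lipid_or_dw_fraction: float
    reference_fraction: float
    target_tl: float
    c_adj: float  # µg/kg on the normalized basis
    mode: AdjustmentMode
    ci: Optional[tuple[float, float]] = None


def adjust_to_reference(
    c_meas: float,
    tl_x: float,
    tmf: float,
    fraction: float,
    mode: AdjustmentMode = AdjustmentMode.lipid,
    target_tl: float = FRESHWATER_TARGET_TL,
    tmf_ci: Optional[tuple[float, float]] = None,
    reference_fraction: Optional[float] = None,
) -> AdjustmentResult:
    """Adjust a wet-weight measurement to the reference TL and basis.

    ``fraction`` is the monitored organism's lipid fraction (mode
    ``lipid``) or dry-weight fraction (mode ``dry_weight``).  If
    ``tmf_ci`` is given, the interval is propagated through the same
    monotone power transform (exact endpoint mapping, no delta-method
    approximation) and attached to the result.
    """
    mode = AdjustmentMode(mode)
    if tmf <= 0:
        raise ValueError("TMF must be positive")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if reference_fraction is None:
        reference_fraction = (
            REFERENCE_LIPID_FRACTION
            if mode == AdjustmentMode.lipid
            else REFERENCE_DRY_FRACTION
        )

    def _adjust(t: float) -> float:
        return c_meas * t ** (target_tl - tl_x) * reference_fraction / fraction

    ci = None
    if tmf_ci is not None:
        lo, hi = _adjust(tmf_ci[0]), _adjust(tmf_ci[1])
        ci = (min(lo, hi), max(lo, hi))
    return AdjustmentResult(
        c_meas=c_meas,
        tl_x=tl_x,
        tmf_applied=tmf,
        lipid_or_dw_fraction=fraction,
        reference_fraction=reference_fraction,
        target_tl=target_tl,
        c_adj=_adjust(tmf),
        mode=mode,
        ci=ci,
    )


def translate_eqs(eqs_value: float, from_tl: float, to_tl: float, tmf: float) -> float:
    """Express an EQS set at ``from_tl`` as a concentration at ``to_tl``.

    Uses the same biomagnification power law: EQS@to = EQS@from ×
    TMF^(to − from).  Exact inverse of translating back.
    """
    if tmf <= 0:
        raise ValueError("TMF must be positive")
    return eqs_value * tmf ** (to_tl - from_tl)


@dataclass(frozen=True)
class ComplianceResult:
    verdict: ComplianceVerdict
    margin: float  # c_adj / eqs_value (point estimate)
    c_adj: float
    eqs_value: float
    ci: Optional[tuple[float, float]] = None


def compare_to_eqs(adjusted: AdjustmentResult, eqs_value: float) -> ComplianceResult:
    """Compare an adjusted concentration against an EQS.

    Point comparison of c_adj versus the standard; when the adjustment
    carries a CI that straddles the standard, the verdict is
    ``indeterminate`` with both bounds reported — a deliberately
    conservative report, since under-calling exceedances (Type II
    error) is the less protective mistake.
    """
    if eqs_value <= 0:
        raise ValueError("EQS value must be positive")
    margin = adjusted.c_adj / eqs_value
    if adjusted.ci is not None and adjusted.ci[0] <= eqs_value <= adjusted.ci[1]:
        verdict = ComplianceVerdict.indeterminate
    elif adjusted.c_adj <= eqs_value:
        verdict = ComplianceVerdict.compliant
    else:
        verdict = ComplianceVerdict.non_compliant
    return ComplianceResult(
        verdict=verdict,
        margin=margin,
        c_adj=adjusted.c_adj,
        eqs_value=eqs_value,
        ci=adjusted.ci,
    )
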