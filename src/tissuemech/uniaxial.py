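"""Uniaxial tension: bilinear (toe + linear) fit of engineering stress-strain.

Soft collagenous tissue in tension shows a compliant low-strain "toe"
regime, where crimped fibers unfold, followed by a stiffer linear regime
once fibers align. Both slopes are Young's moduli; the toe slope is the one
comparable to small-strain techniques (indentation, SAOS, cavitation).

The fit is a continuous two-segment least squares: a grid search over
candidate breakpoints (the interior strain values, restricted to the
central 10%-90% of the strain range), a closed-form linear fit for each
candidate, then a continuous refinement of the breakpoint within the
bracketing grid interval. Points after the global stress maximum (rupture
tail) are truncated before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datamodel import (
    DomainError,
    InsufficientDataError,
    StressStrainCurve,
)

__all__ = ["UniaxialResult", "fit_bilinear", "uniaxial_strain_rate"]


@dataclass(frozen=True)
class UniaxialResult:
    toe_modulus: float
    linear_modulus: float
    transition_strain: float  # NaN when not identifiable
    sse: float
    identifiable: bool
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.toe_modulus > 0:
            raise DomainError(f"toe_modulus must be > 0, got {self.toe_modulus}")

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "toe_modulus_pa": self.toe_modulus,
            "linear_modulus_pa": self.linear_modulus,
            "transition_strain": self.transition_strain,
            "sse_pa2": self.sse,
            "identifiable": self.identifiable,
        }


def _segment_fit(strain: np.ndarray, stress: np.ndarray, eb: float):
    """Closed-form continuous two-segment LS at fixed breakpoint eb.

    Model: stress = c + m1*min(strain, eb) + m2*max(strain - eb, 0).
    Returns (sse, c, m1, m2).
    """
    x1 = np.minimum(strain, eb)
    x2 = np.maximum(strain - eb, 0.0)
    X = np.column_stack([np.ones_like(strain), x1, x2])
    coef, _, _, _ = np.linalg.lstsq(X, stress, rcond=None)
    resid = stress - X @ coef
    return float(resid @ resid), coef


def fit_bilinear(curve: StressStrainCurve, breakpoint_margin: float = 0.10) -> UniaxialResult:
    """Continuous two-segment least-squares fit of a stress-strain curve.

    Returns the toe slope, linear slope, transition strain and SSE. When the
    two slopes differ by less than 10% the curve is flagged unidentifiable
    and both moduli are set to the single-line slope (transition NaN).
    """
    strain = curve.strain
    stress = curve.stress
    # truncate the rupture tail after the global stress maximum
    peak = int(np.argmax(stress))
    strain, stress = strain[: peak + 1], stress[: peak + 1]
    if len(strain) < 10:
        raise InsufficientDataError(
            f"bilinear fit needs >= 10 points before the stress peak, got {len(strain)}"
        )

    lo = strain[0] + breakpoint_margin * (strain[-1] - strain[0])
    hi = strain[0] + (1.0 - breakpoint_margin) * (strain[-1] - strain[0])
    candidates = np.unique(strain[(strain > lo) & (strain < hi)])
    if len(candidates) == 0:
        candidates = np.array([0.5 * (lo + hi)])

    sses = np.array([_segment_fit(strain, stress, eb)[0] for eb in candidates])
    j = int(np.argmin(sses))

    # continuous refinement within the bracketing interval
    lo_b = candidates[j - 1] if j > 0 else lo
    hi_b = candidates[j + 1] if j < len(candidates) - 1 else hi
    res = optimize.minimize_scalar(
        lambda eb: _segment_fit(strain, stress, eb)[0],
        bounds=(lo_b, hi_b),
        method="bounded",
        options={"xatol": 1e-12},
    )
    eb = float(res.x) if res.fun <= sses[j] else float(candidates[j])
    # extra candidate: intersection of the two segment lines fit
    # independently on the partition implied by eb (exact on clean bilinear
    # data, where Brent stalls on the flat numerical floor of the SSE)
    left, right = strain < eb, strain >= eb
    if left.sum() >= 2 and right.sum() >= 2:
        s1, b1 = np.polyfit(strain[left], stress[left], 1)
        s2, b2 = np.polyfit(strain[right], stress[right], 1)
        if abs(s1 - s2) > 0:
            eb_x = (b2 - b1) / (s1 - s2)
            if lo <= eb_x <= hi and _segment_fit(strain, stress, eb_x)[0] <= res.fun:
                eb = float(eb_x)
    # model: c + m1*min(e, eb) + m2*max(e-eb, 0); min() is flat above the
    # breakpoint, so each coefficient IS its segment's slope
    sse, (c, m1, m2) = _segment_fit(strain, stress, eb)

    # single-line fit for the identifiability check
    line = np.polyfit(strain, stress, 1)
    line_slope = float(line[0])
    sse_line = float(np.sum((np.polyval(line, strain) - stress) ** 2))

    scale = max(abs(m1), abs(m2))
    identifiable = scale > 0 and abs(m2 - m1) >= 0.10 * scale
    if not identifiable:
        return UniaxialResult(
            toe_modulus=line_slope,
            linear_modulus=line_slope,
            transition_strain=float("nan"),
            sse=sse_line,
            identifiable=False,
            sample_id=curve.sample_id,
        )
    return UniaxialResult(
        toe_modulus=float(m1),
        linear_modulus=float(m2),
        transition_strain=eb,
        sse=sse,
        identifiable=True,
        sample_id=curve.sample_id,
    )


def uniaxial_strain_rate(displacement_rate: float, gauge_length: float) -> float:
    """Engineering strain rate: global displacement rate over gauge length.

    Straining at 1% of the starting length per second gives 0.01 1/s.
    """
    if not gauge_length > 0:
        raise DomainError(f"gauge length must be > 0, got {gauge_length}")
    if displacement_rate < 0:
        raise DomainError(f"displacement rate must be >= 0, got {displacement_rate}")
    return displacement_rate / gauge_length
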