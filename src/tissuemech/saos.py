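"""Small-amplitude oscillatory shear: sweeps -> |G*|, Young's modulus, power law.

The magnitude of the complex shear modulus is |G*| = sqrt(G'^2 + G''^2) and
converts to a Young's modulus through E = 2 G* (1 + nu). Soft tissues show a
weak power-law frequency dependence |G*| = A * omega^beta; the exponent beta
(~0.11 for lung parenchyma) is later used to normalize moduli measured at
different strain rates onto a common reference frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import (
    AnalysisConfig,
    DomainError,
    InsufficientDataError,
    OscillatorySweep,
    TissueMechError,
)

__all__ = [
    "PowerLawFit",
    "SAOSResult",
    "ExtrapolationError",
    "young_from_shear",
    "complex_modulus",
    "fit_power_law",
    "check_linear_regime",
    "analyze_sweep",
]


class ExtrapolationError(TissueMechError, ValueError):
    """Requested frequency lies outside the measured sweep range."""


@dataclass(frozen=True)
class PowerLawFit:
    """|G*| = A * omega^beta fit in log-log space."""

    A: float  # Pa * s^beta
    beta: float
    A_se: float  # standard error of A (delta method from log-intercept SE)
    beta_se: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "A_pa_s_beta": self.A,
            "beta": self.beta,
            "A_se": self.A_se,
            "beta_se": self.beta_se,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class SAOSResult:
    G_star: float
    young_modulus: float
    poisson_ratio: float
    reference_frequency: float
    powerlaw: PowerLawFit
    sample_id: str = ""

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "g_star_pa": self.G_star,
            "young_modulus_pa": self.young_modulus,
            "poisson_ratio": self.poisson_ratio,
            "reference_frequency_hz": self.reference_frequency,
            "powerlaw": self.powerlaw.to_dict(),
        }


def young_from_shear(G_star: float, nu: float = 0.42) -> float:
    """Young's modulus from the complex shear modulus: E = 2 G* (1 + nu)."""
    if not 0 <= nu <= 0.5:
        raise DomainError(f"poisson ratio must be in [0, 0.5], got {nu}")
    if G_star < 0:
        raise DomainError(f"G* must be >= 0, got {G_star}")
    return 2.0 * G_star * (1.0 + nu)


def complex_modulus(sweep: OscillatorySweep, at_frequency: float) -> float:
    """|G*| = sqrt(G'^2 + G''^2) at a requested frequency.

    Between measured points the magnitude is interpolated linearly in
    log-log space (power-law materials are straight lines there). Requests
    outside the sweep range raise :class:`ExtrapolationError`.
    """
    f = sweep.frequency
    if not (f[0] <= at_frequency <= f[-1]):
        raise ExtrapolationError(
            f"frequency {at_frequency} Hz outside sweep range "
            f"[{f[0]}, {f[-1]}] Hz"
        )
    mag = np.hypot(sweep.storage_modulus_gprime, sweep.loss_modulus_gdoubleprime)
    exact = np.isclose(f, at_frequency, rtol=1e-12, atol=0.0)
    if exact.any():
        return float(mag[np.argmax(exact)])
    if (mag <= 0).any():
        raise DomainError("log-log interpolation requires positive |G*| values")
    return float(
        np.exp(np.interp(np.log(at_frequency), np.log(f), np.log(mag)))
    )


def fit_power_law(sweep: OscillatorySweep) -> PowerLawFit:
    """Fit |G*| = A * omega^beta by linear regression of log|G*| on log omega."""
    if len(sweep) < 3:
        raise InsufficientDataError(
            f"power-law fit needs >= 3 frequencies, got {len(sweep)}"
        )
    mag = np.hypot(sweep.storage_modulus_gprime, sweep.loss_modulus_gdoubleprime)
    if (mag <= 0).any():
        raise DomainError("power-law fit requires strictly positive |G*|")
    res = stats.linregress(np.log(sweep.frequency), np.log(mag))
    A = float(np.exp(res.intercept))
    return PowerLawFit(
        A=A,
        beta=float(res.slope),
        A_se=A * float(res.intercept_stderr),
        beta_se=float(res.stderr),
        n_points=len(sweep),
    )


def check_linear_regime(
    strain_amplitude: np.ndarray,
    gprime: np.ndarray,
    tolerance: float = 0.10,
    probe_strain: float = 0.005,
) -> tuple[float, bool]:
    """Largest strain amplitude still on the low-strain G' plateau.

    The plateau is the mean G' of the 3 smallest amplitudes; the limit
    strain is the largest amplitude up to which G' stays within
    ``tolerance`` of the plateau *contiguously from the smallest amplitude*.
    Returns ``(limit_strain, probe_strain <= limit_strain)`` — by default
    whether the protocol's 0.5% strain amplitude sits in the linear regime.
    """
    amp = np.asarray(strain_amplitude, dtype=float)
    gp = np.asarray(gprime, dtype=float)
    if len(amp) != len(gp):
        raise DomainError("strain_amplitude and gprime lengths differ")
    if len(amp) < 3:
        raise InsufficientDataError("linear-regime check needs >= 3 amplitudes")
    order = np.argsort(amp)
    amp, gp = amp[order], gp[order]
    plateau = float(np.mean(gp[:3]))
    if plateau <= 0:
        raise DomainError("non-positive low-strain plateau")
    within = np.abs(gp - plateau) <= tolerance * plateau
    if not within[0]:
        limit = float(amp[0])
    else:
        breaks = np.flatnonzero(~within)
        last = (breaks[0] - 1) if len(breaks) else (len(amp) - 1)
        limit = float(amp[last])
    return limit, probe_strain <= limit


def analyze_sweep(
    sweep: OscillatorySweep, config: AnalysisConfig | None = None
) -> SAOSResult:
    """|G*| at the reference frequency -> E = 2 G* (1 + nu), plus power-law fit."""
    config = config or AnalysisConfig()
    g_star = complex_modulus(sweep, config.reference_frequency)
    return SAOSResult(
        G_star=g_star,
        young_modulus=young_from_shear(g_star, config.poisson_ratio),
        poisson_ratio=config.poisson_ratio,
        reference_frequency=config.reference_frequency,
        powerlaw=fit_power_law(sweep),
        sample_id=sweep.sample_id,
    )
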