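"""Shared domain types, unit conventions and analysis configuration.

All quantities are stored in SI units (Pa, m, s, N, Hz). Unit conversion
happens exclusively in the CSV readers (:mod:`tissuemech.io`); every other
module may assume SI throughout.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "TissueMechError",
    "FormatError",
    "ValidationError",
    "ConfigurationError",
    "DomainError",
    "InsufficientDataError",
    "Technique",
    "Condition",
    "PressureTrace",
    "ForceCurve",
    "OscillatorySweep",
    "StressStrainCurve",
    "AnalysisConfig",
    "ModulusRecord",
    "PSI_TO_PA",
    "UL_PER_MIN_TO_M3_PER_S",
    "PROTOCOL_INJECTION_RATE_M3S",
]

# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class TissueMechError(Exception):
    """Base class for all package errors."""


class FormatError(TissueMechError, ValueError):
    """A file or table does not have the expected columns/shape."""


class ValidationError(TissueMechError, ValueError):
    """A domain object violates one of its invariants."""


class ConfigurationError(TissueMechError, ValueError):
    """An analysis setting is inconsistent with the data (e.g. cutoff >= Nyquist)."""


class DomainError(TissueMechError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientDataError(TissueMechError, ValueError):
    """Not enough points / groups / radii for the requested fit."""


# --------------------------------------------------------------------------
# Unit constants
# --------------------------------------------------------------------------

PSI_TO_PA = 6894.757293168
UL_PER_MIN_TO_M3_PER_S = 1e-9 / 60.0
#: 5000 uL/min, the air injection rate of the cavitation protocol, in m^3/s.
PROTOCOL_INJECTION_RATE_M3S = 5000.0 * UL_PER_MIN_TO_M3_PER_S


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def _first_violation(mask: np.ndarray) -> int:
    return int(np.flatnonzero(mask)[0])


# --------------------------------------------------------------------------
# Enums
# --------------------------------------------------------------------------


class Technique(str, enum.Enum):
    """The five modulus-producing measurement channels."""

    CAVITATION = "cavitation"
    INDENTATION = "indentation"
    SAOS = "saos"
    UNIAXIAL_TOE = "uniaxial_toe"
    UNIAXIAL_LINEAR = "uniaxial_linear"


class Condition(str, enum.Enum):
    """Tissue handling condition prior to testing."""

    FRESH = "fresh"
    FROZEN_LN2 = "frozen_LN2"
    FROZEN_OCT = "frozen_OCT"
    FROZEN_MINUS80 = "frozen_minus80"


# --------------------------------------------------------------------------
# Signal containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PressureTrace:
    """A cavitation pressure-time record for one needle insertion.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing.
    pressure : array of float
        Gauge pressure in Pa.
    needle_radius : float
        Inner radius of the needle shaft in m.
    injection_rate : float
        Volumetric air injection rate in m^3/s.
    """

    time: np.ndarray
    pressure: np.ndarray
    needle_radius: float
    injection_rate: float
    sample_id: str
    region_id: str = ""
    filtered: bool = False

    def __post_init__(self) -> None:
        t = _as_float_array(self.time, "time")
        p = _as_float_array(self.pressure, "pressure")
        if len(t) != len(p):
            raise ValidationError(
                f"time ({len(t)}) and pressure ({len(p)}) lengths differ"
            )
        if len(t) < 10:
            raise ValidationError(f"trace needs >= 10 samples, got {len(t)}")
        bad = np.diff(t) <= 0
        if bad.any():
            raise ValidationError(
                f"time must be strictly increasing; first violation at index "
                f"{_first_violation(bad) + 1}"
            )
        if not self.needle_radius > 0:
            raise ValidationError(f"needle_radius must be > 0, got {self.needle_radius}")
        if not self.injection_rate > 0:
            raise ValidationError(
                f"injection_rate must be > 0, got {self.injection_rate}"
            )
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "pressure", p)

    def __len__(self) -> int:
        return len(self.time)

    @property
    def median_dt(self) -> float:
        """Median sampling interval in s (sampling may be non-uniform)."""
        return float(np.median(np.diff(self.time)))

    @property
    def nyquist(self) -> float:
        """Nyquist frequency in Hz implied by the median sampling interval."""
        return 0.5 / self.median_dt


@dataclass(frozen=True)
class ForceCurve:
    """A micro-indentation force-displacement record.

    ``displacement`` is the *stage* displacement; the sample deflection is
    obtained downstream by subtracting the cantilever deflection F/k.
    ``cantilever_stiffness`` may be ``math.inf`` for a rigid column.
    """

    displacement: np.ndarray
    force: np.ndarray
    indenter_radius_a: float
    sample_thickness_h: float
    cantilever_stiffness: float = math.inf
    indentation_rate: float = 20e-6
    sample_id: str = ""

    def __post_init__(self) -> None:
        d = _as_float_array(self.displacement, "displacement")
        f = _as_float_array(self.force, "force")
        if len(d) != len(f):
            raise ValidationError(
                f"displacement ({len(d)}) and force ({len(f)}) lengths differ"
            )
        bad = np.diff(d) < 0
        if bad.any():
            raise ValidationError(
                "displacement must be non-decreasing; first violation at index "
                f"{_first_violation(bad) + 1}"
            )
        if not self.indenter_radius_a > 0:
            raise ValidationError("indenter_radius_a must be > 0")
        if not self.sample_thickness_h > 0:
            raise ValidationError("sample_thickness_h must be > 0")
        if not self.cantilever_stiffness > 0:
            raise ValidationError("cantilever_stiffness must be > 0 (inf = rigid)")
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "force", f)

    def __len__(self) -> int:
        return len(self.displacement)


@dataclass(frozen=True)
class OscillatorySweep:
    """A small-amplitude oscillatory shear frequency sweep (G', G'' vs f)."""

    frequency: np.ndarray
    storage_modulus_gprime: np.ndarray
    loss_modulus_gdoubleprime: np.ndarray
    strain_amplitude: float = 0.005
    temperature: float = 25.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        f = _as_float_array(self.frequency, "frequency")
        gp = _as_float_array(self.storage_modulus_gprime, "storage_modulus_gprime")
        gpp = _as_float_array(
            self.loss_modulus_gdoubleprime, "loss_modulus_gdoubleprime"
        )
        if not (len(f) == len(gp) == len(gpp)):
            raise ValidationError("frequency / G' / G'' lengths differ")
        if (f <= 0).any():
            raise ValidationError("frequencies must be > 0")
        bad = np.diff(f) <= 0
        if bad.any():
            raise ValidationError(
                "frequency must be strictly increasing; first violation at index "
                f"{_first_violation(bad) + 1}"
            )
        if (gp < 0).any() or (gpp < 0).any():
            raise ValidationError("moduli must be >= 0")
        object.__setattr__(self, "frequency", f)
        object.__setattr__(self, "storage_modulus_gprime", gp)
        object.__setattr__(self, "loss_modulus_gdoubleprime", gpp)

    def __len__(self) -> int:
        return len(self.frequency)


@dataclass(frozen=True)
class StressStrainCurve:
    """An engineering stress-strain record from uniaxial tension."""

    strain: np.ndarray
    stress: np.ndarray
    gauge_length: float
    cross_section_area: float
    strain_rate: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        eps = _as_float_array(self.strain, "strain")
        sig = _as_float_array(self.stress, "stress")
        if len(eps) != len(sig):
            raise ValidationError("strain and stress lengths differ")
        if len(eps) == 0:
            raise ValidationError("empty stress-strain curve")
        if abs(eps[0]) > 1e-12:
            raise ValidationError(f"strain must start at 0, got {eps[0]}")
        bad = np.diff(eps) < 0
        if bad.any():
            raise ValidationError(
                "strain must be non-decreasing; first violation at index "
                f"{_first_violation(bad) + 1}"
            )
        object.__setattr__(self, "strain", eps)
        object.__setattr__(self, "stress", sig)

    def __len__(self) -> int:
        return len(self.strain)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Tunable settings for every analysis stage.

    Defaults follow the study protocol where one is stated (Poisson ratio
    0.42, SAOS reference frequency 0.1 Hz) and otherwise are this package's
    documented choices.
    """

    poisson_ratio: float = 0.42
    reference_frequency: float = 0.1

    # Butterworth low-pass applied to pressure traces before event detection.
    butterworth_order: int = 2
    butterworth_cutoff_hz: float | None = None  # None -> min(10 Hz, 0.1 * Nyquist)

    # Cavitation event detection.
    drop_fraction: float = 0.10
    drop_window_s: float = 0.25
    baseline_fraction: float = 0.05

    # Indentation contact detection and compliance window.
    contact_noise_multiplier: float = 3.0
    contact_persistence: int = 5
    contact_baseline_fraction: float = 0.10
    compliance_window: tuple[float, float] = (0.2, 0.8)
    eq4_grouping: str = "shull"  # "shull" (half-space-limit reading) | "literal"

    # SAOS linear-regime check.
    linear_regime_tolerance: float = 0.10

    # Bilinear fit breakpoint bounds as fractions of the strain range.
    breakpoint_margin: float = 0.10

    # Cross-platform normalization.
    powerlaw_beta_default: float = 0.11
    bonferroni: bool = False

    random_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValidationError(
                f"poisson_ratio must be in [0, 0.5], got {self.poisson_ratio}"
            )
        if self.poisson_ratio == 0.5:
            warnings.warn(
                "poisson_ratio = 0.5: the 2.8(1-2nu)(a/h) confinement term "
                "vanishes; the indentation correction loses its compressibility "
                "contribution",
                stacklevel=2,
            )
        if not self.reference_frequency > 0:
            raise ValidationError("reference_frequency must be > 0")
        if not 0 < self.drop_fraction < 1:
            raise ValidationError("drop_fraction must be in (0, 1)")
        lo, hi = self.compliance_window
        if not 0 <= lo < hi <= 1:
            raise ValidationError("compliance_window must satisfy 0 <= lo < hi <= 1")
        if self.eq4_grouping not in ("shull", "literal"):
            raise ValidationError("eq4_grouping must be 'shull' or 'literal'")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "compliance_window" in kwargs:
            kwargs["compliance_window"] = tuple(kwargs["compliance_window"])
        return cls(**kwargs)


# --------------------------------------------------------------------------
# Result record shared across techniques
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModulusRecord:
    """One per-sample, per-technique Young's modulus row.

    ``strain_rate`` is the technique's characteristic rate in 1/s (treated as
    Hz-equivalent for the power-law normalization);
    ``rate_adjusted_modulus`` is filled by the cross-platform stage.
    """

    technique: Technique
    sample_id: str
    young_modulus: float
    strain_rate: float
    region_id: str = ""
    rate_adjusted_modulus: float | None = None
    condition: Condition = Condition.FRESH

    def __post_init__(self) -> None:
        tech = Technique(self.technique)
        cond = Condition(self.condition)
        object.__setattr__(self, "technique", tech)
        object.__setattr__(self, "condition", cond)
        if not self.young_modulus > 0:
            raise ValidationError(
                f"young_modulus must be > 0, got {self.young_modulus}"
            )

    def to_dict(self) -> dict:
        return {
            "technique": self.technique.value,
            "sample_id": self.sample_id,
            "region_id": self.region_id,
            "young_modulus_pa": self.young_modulus,
            "strain_rate_per_s": self.strain_rate,
            "rate_adjusted_modulus_pa": self.rate_adjusted_modulus,
            "condition": self.condition.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModulusRecord":
        return cls(
            technique=Technique(d["technique"]),
            sample_id=d["sample_id"],
            region_id=d.get("region_id", ""),
            young_modulus=d["young_modulus_pa"],
            strain_rate=d["strain_rate_per_s"],
            rate_adjusted_modulus=d.get("rate_adjusted_modulus_pa"),
            condition=Condition(d.get("condition", "fresh")),
        )
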