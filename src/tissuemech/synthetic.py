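"""Seeded synthetic instrument signals with known ground truth.

Every analysis stage in this package is validated by parameter recovery:
the generators below emit cavitation pressure traces, indentation force
curves, SAOS frequency sweeps and uniaxial stress-strain curves from a
:class:`MaterialGroundTruth`, and the corresponding analysis modules must
recover the generating parameters (exactly at zero noise, statistically at
the default noise levels).

The presets encode the study conditions of the porcine-lung and PEG
hydrogel experiments: per-technique Young's moduli (cavitation 6.1 kPa,
indentation 1.4 kPa, SAOS 3.3 kPa at 0.1 Hz, uniaxial toe 3.4 kPa for
lung; 19.1 / 13.9 kPa for the hydrogel), the four (lung) or three
(hydrogel) needle inner radii of the protocol, a power-law exponent
beta = 0.11, and a Poisson ratio of 0.42.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as tmio
from .cavitation import predict_critical_pressure
from .datamodel import (
    PROTOCOL_INJECTION_RATE_M3S,
    DomainError,
    ForceCurve,
    OscillatorySweep,
    PressureTrace,
    StressStrainCurve,
    ValidationError,
)
from .indentation import compliance_from_modulus

__all__ = [
    "MaterialGroundTruth",
    "LUNG_NEEDLE_RADII_M",
    "HYDROGEL_NEEDLE_RADII_M",
    "gen_cavitation_trace",
    "gen_force_curve",
    "gen_oscillatory_sweep",
    "gen_stress_strain",
    "gen_study",
    "preset_design",
]

#: Needle inner radii (m) for the lung protocol: 16, 18, 22, 26 gauge
#: (inner diameters 1.194, 0.838, 0.413, 0.260 mm).
LUNG_NEEDLE_RADII_M = (0.597e-3, 0.419e-3, 0.2065e-3, 0.130e-3)

#: Flat needle inner radii (m) for the hydrogel protocol: 24, 27, 30 gauge
#: (inner diameters 0.311, 0.210, 0.159 mm).
HYDROGEL_NEEDLE_RADII_M = (0.1555e-3, 0.105e-3, 0.0795e-3)


@dataclass(frozen=True)
class MaterialGroundTruth:
    """Generating parameters for one synthetic material.

    The loss tangent (default 0.2) is a free synthetic parameter — the study
    reports G' and G'' but no numeric ratio. Noise defaults (pressure sd 2%
    of Pc, force sd 1% of max force, multiplicative modulus sd 5%, stress sd
    2% of peak stress) are chosen to make recovery nontrivial but stable.
    """

    E_true: float = 6.1e3
    surface_tension_true: float = 0.02
    poisson_ratio: float = 0.42
    powerlaw_A: float = 1.5e3
    powerlaw_beta: float = 0.11
    toe_modulus_true: float = 3.4e3
    linear_modulus_true: float = 30e3
    transition_strain_true: float = 0.15
    loss_tangent: float = 0.2
    pressure_noise_fraction: float = 0.02
    force_noise_fraction: float = 0.01
    modulus_noise_fraction: float = 0.05
    stress_noise_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("E_true", "powerlaw_A", "toe_modulus_true", "linear_modulus_true"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 < self.transition_strain_true:
            raise ValidationError("transition_strain_true must be > 0")
        if self.powerlaw_beta < 0:
            raise ValidationError("powerlaw_beta must be >= 0")
        if self.surface_tension_true < 0 or self.loss_tangent < 0:
            raise ValidationError("surface tension and loss tangent must be >= 0")
        for name in (
            "pressure_noise_fraction",
            "force_noise_fraction",
            "modulus_noise_fraction",
            "stress_noise_fraction",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def gen_cavitation_trace(
    truth: MaterialGroundTruth,
    needle_radius: float,
    duration: float = 15.0,
    n_samples: int = 1500,
    seed: int = 0,
    drop_fraction_after: float = 0.2,
    ramp_shape: float = 3.0,
    injection_rate: float = PROTOCOL_INJECTION_RATE_M3S,
    sample_id: str = "synthetic",
    region_id: str = "",
) -> PressureTrace:
    """Pressure-time trace ramping to the critical pressure, then dropping.

    The ramp is a smooth saturating exponential reaching exactly
    Pc = 1.05 E_true + 2.1 gamma / r at 80% of the duration, after which the
    pressure drops within one sample interval to ``drop_fraction_after``*Pc
    and stays there. Gaussian sensor noise with sd =
    ``pressure_noise_fraction * Pc`` is added throughout.
    """
    if not needle_radius > 0:
        raise DomainError(f"needle radius must be > 0, got {needle_radius}")
    pc = predict_critical_pressure(
        truth.E_true, truth.surface_tension_true, needle_radius
    )
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_samples)
    # pin the event to a grid sample so the noiseless peak is exactly Pc
    t_event = t[int(round(0.8 * (n_samples - 1)))]
    k = ramp_shape
    ramp = (1.0 - np.exp(-k * t / t_event)) / (1.0 - np.exp(-k))
    p = np.where(t <= t_event, pc * ramp, drop_fraction_after * pc)
    p = p + rng.normal(0.0, truth.pressure_noise_fraction * pc, n_samples)
    return PressureTrace(
        time=t,
        pressure=p,
        needle_radius=needle_radius,
        injection_rate=injection_rate,
        sample_id=sample_id,
        region_id=region_id,
    )


def gen_force_curve(
    truth: MaterialGroundTruth,
    indenter_radius_a: float = 0.5e-3,
    sample_thickness_h: float = 2.0e-3,
    cantilever_stiffness: float = math.inf,
    max_force: float = 2.0e-3,
    seed: int = 0,
    n_points: int = 500,
    contact_offset: float = 0.3e-3,
    indentation_rate: float = 20e-6,
    sample_id: str = "synthetic",
) -> ForceCurve:
    """Indentation force-displacement curve with cantilever compliance in series.

    Pre-contact: stage travels to ``contact_offset`` with baseline force
    noise only. Post-contact: sample deflection delta_s = C*F with C the
    closed-form inverse of the confinement-corrected modulus relation at
    (E_true, a, h, nu); the recorded stage displacement is
    ``contact_offset + C*F + F/k``. Gaussian force noise with sd =
    ``force_noise_fraction * max_force``.
    """
    if not (indenter_radius_a > 0 and sample_thickness_h > 0):
        raise DomainError("indenter radius and sample thickness must be > 0")
    if not cantilever_stiffness > 0:
        raise DomainError("cantilever stiffness must be > 0 (inf = rigid)")
    if not max_force > 0:
        raise DomainError("max_force must be > 0")
    C = compliance_from_modulus(
        truth.E_true, indenter_radius_a, sample_thickness_h, truth.poisson_ratio
    )
    rng = np.random.default_rng(seed)
    n_pre = n_points // 5
    n_post = n_points - n_pre
    d_pre = np.linspace(0.0, contact_offset, n_pre, endpoint=False)
    f_post = np.linspace(0.0, max_force, n_post)
    inv_k = 0.0 if math.isinf(cantilever_stiffness) else 1.0 / cantilever_stiffness
    d_post = contact_offset + C * f_post + inv_k * f_post
    force = np.concatenate([np.zeros(n_pre), f_post])
    force = force + rng.normal(0.0, truth.force_noise_fraction * max_force, n_points)
    return ForceCurve(
        displacement=np.concatenate([d_pre, d_post]),
        force=force,
        indenter_radius_a=indenter_radius_a,
        sample_thickness_h=sample_thickness_h,
        cantilever_stiffness=cantilever_stiffness,
        indentation_rate=indentation_rate,
        sample_id=sample_id,
    )


def gen_oscillatory_sweep(
    truth: MaterialGroundTruth,
    frequencies: Sequence[float] | None = None,
    seed: int = 0,
    strain_amplitude: float = 0.005,
    temperature: float = 25.0,
    sample_id: str = "synthetic",
) -> OscillatorySweep:
    """Frequency sweep with |G*| = A * omega^beta and constant loss tangent.

    The magnitude is split into G' = |G*|/sqrt(1 + tan^2 delta) and
    G'' = G' * tan delta; one multiplicative log-normal factor per frequency
    (sd ``modulus_noise_fraction``) scales both components, preserving the
    loss tangent while perturbing the magnitude.
    """
    if frequencies is None:
        frequencies = np.linspace(0.1, 1.0, 10)
    freq = np.asarray(frequencies, dtype=float)
    if len(freq) == 0:
        raise DomainError("frequency list must not be empty")
    if (freq <= 0).any():
        raise DomainError("frequencies must be > 0")
    rng = np.random.default_rng(seed)
    mag = truth.powerlaw_A * freq**truth.powerlaw_beta
    mag = mag * np.exp(rng.normal(0.0, truth.modulus_noise_fraction, len(freq)))
    gp = mag / np.sqrt(1.0 + truth.loss_tangent**2)
    gpp = gp * truth.loss_tangent
    return OscillatorySweep(
        frequency=freq,
        storage_modulus_gprime=gp,
        loss_modulus_gdoubleprime=gpp,
        strain_amplitude=strain_amplitude,
        temperature=temperature,
        sample_id=sample_id,
    )


def gen_stress_strain(
    truth: MaterialGroundTruth,
    max_strain: float = 0.4,
    n_points: int = 200,
    seed: int = 0,
    gauge_length: float = 27e-3,
    cross_section_area: float = 20e-6,
    strain_rate: float = 0.01,
    sample_id: str = "synthetic",
) -> StressStrainCurve:
    """Continuous bilinear engineering stress-strain curve with additive noise.

    Slope ``toe_modulus_true`` below ``transition_strain_true``,
    ``linear_modulus_true`` above; Gaussian stress noise with sd =
    ``stress_noise_fraction`` * peak stress.
    """
    if not max_strain > truth.transition_strain_true:
        raise DomainError(
            "max_strain must exceed the transition strain "
            f"({truth.transition_strain_true})"
        )
    rng = np.random.default_rng(seed)
    strain = np.linspace(0.0, max_strain, n_points)
    et = truth.transition_strain_true
    stress = np.where(
        strain <= et,
        truth.toe_modulus_true * strain,
        truth.toe_modulus_true * et + truth.linear_modulus_true * (strain - et),
    )
    stress = stress + rng.normal(
        0.0, truth.stress_noise_fraction * stress.max(), n_points
    )
    return StressStrainCurve(
        strain=strain,
        stress=stress,
        gauge_length=gauge_length,
        cross_section_area=cross_section_area,
        strain_rate=strain_rate,
        sample_id=sample_id,
    )


# --------------------------------------------------------------------------
# Study-level generation
# --------------------------------------------------------------------------


def preset_design(preset: str) -> dict:
    """Study design emulating the lung or hydrogel experiment at desk scale.

    Each technique block carries its own ground truth (the per-technique
    mean moduli the study reports serve as generating values), replicate
    counts and geometry. Replicate counts are scaled-down stand-ins for the
    animal-level design.
    """
    if preset == "lung":
        base = MaterialGroundTruth()
        return {
            "cavitation": {
                "truth": dataclasses.replace(base, E_true=6.1e3),
                "n_regions": 8,
                "needle_radii_m": list(LUNG_NEEDLE_RADII_M),
                "traces_per_radius": 3,
            },
            "indentation": {
                "truth": dataclasses.replace(base, E_true=1.4e3),
                "n_samples": 6,
                "indents_per_sample": 3,
                "indenter_radius_m": 0.5e-3,
                "sample_thickness_m": 2.0e-3,
                "cantilever_stiffness_n_per_m": 10.0,
                "max_force_n": 2.0e-3,
            },
            "saos": {
                # A chosen so that E = 2*|G*|(0.1 Hz)*(1+nu) equals 3.3 kPa
                "truth": dataclasses.replace(
                    base,
                    powerlaw_A=(3.3e3 / (2.0 * 1.42)) / 0.1**0.11,
                ),
                "n_samples": 7,
                "frequencies_hz": list(np.round(np.linspace(0.1, 1.0, 10), 6)),
            },
            "uniaxial": {
                "truth": dataclasses.replace(
                    base,
                    toe_modulus_true=3.4e3,
                    linear_modulus_true=30e3,
                    transition_strain_true=0.15,
                ),
                "n_samples": 4,
                "max_strain": 0.4,
                "gauge_length_m": 27e-3,
                "cross_section_area_m2": 20e-6,
            },
        }
    if preset == "hydrogel":
        base = MaterialGroundTruth(surface_tension_true=0.03)
        return {
            "cavitation": {
                "truth": dataclasses.replace(base, E_true=19.1e3),
                "n_regions": 6,
                "needle_radii_m": list(HYDROGEL_NEEDLE_RADII_M),
                "traces_per_radius": 3,
            },
            "indentation": {
                "truth": dataclasses.replace(base, E_true=13.9e3),
                "n_samples": 6,
                "indents_per_sample": 3,
                "indenter_radius_m": 0.5e-3,
                "sample_thickness_m": 2.0e-3,
                "cantilever_stiffness_n_per_m": 10.0,
                "max_force_n": 2.0e-3,
            },
        }
    raise DomainError(f"unknown preset '{preset}' (expected 'lung' or 'hydrogel')")


def _truth_to_jsonable(truth: MaterialGroundTruth) -> dict:
    return dataclasses.asdict(truth)


def gen_study(
    design: Mapping[str, Mapping],
    out_dir: str | Path,
    seed: int = 0,
    default_truth: MaterialGroundTruth | None = None,
    condition_scales: Mapping[str, float] | None = None,
) -> dict:
    """Write a full synthetic study (CSV tree + ground-truth manifest).

    ``design`` maps technique names to replicate counts and geometry as
    produced by :func:`preset_design`; each block may carry its own
    ``truth`` (falling back to ``default_truth``). Per-sample heterogeneity
    is modeled by drawing each sample's true modulus log-normally around the
    technique truth with sd ``modulus_noise_fraction``.

    ``condition_scales`` optionally maps condition names (e.g.
    ``"frozen_LN2"``) to multiplicative modulus factors; for each named
    condition the indentation samples are re-generated at the scaled
    modulus, emulating a fresh/frozen paired design.

    The tree is deterministic given ``seed`` (no timestamps are written).
    Returns the manifest dictionary, which is also written to
    ``out_dir/manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "techniques": {}, "files": []}

    def _sub(name: str) -> Path:
        p = out / name
        p.mkdir(exist_ok=True)
        return p

    def _sample_E(rng: np.random.Generator, truth: MaterialGroundTruth) -> float:
        return float(
            truth.E_true * np.exp(rng.normal(0.0, truth.modulus_noise_fraction))
        )

    # --- cavitation -------------------------------------------------------
    cav = design.get("cavitation")
    if cav and cav.get("n_regions", 0) > 0:
        truth: MaterialGroundTruth = cav.get("truth", default_truth)
        d = _sub("cavitation")
        rng = np.random.default_rng(root.integers(2**31))
        entries = []
        for i in range(cav["n_regions"]):
            region = f"region{i:02d}"
            e_region = _sample_E(rng, truth)
            region_truth = dataclasses.replace(truth, E_true=e_region)
            for r in cav["needle_radii_m"]:
                for rep in range(cav.get("traces_per_radius", 3)):
                    tseed = int(rng.integers(2**31))
                    trace = gen_cavitation_trace(
                        region_truth,
                        needle_radius=r,
                        seed=tseed,
                        sample_id=region,
                        region_id=region,
                    )
                    stem = f"{region}_r{r*1e3:.4f}mm_rep{rep}"
                    tmio.write_trace_csv(d / f"{stem}.csv", trace)
                    meta = {
                        "needle_radius_m": r,
                        "injection_rate_m3_per_s": trace.injection_rate,
                        "sample_id": region,
                        "region_id": region,
                    }
                    tmio.write_metadata_yaml(d / f"{stem}.meta.yaml", meta)
                    entries.append(
                        {"file": f"cavitation/{stem}.csv", "E_true": e_region, "seed": tseed}
                    )
                    manifest["files"].append(f"cavitation/{stem}.csv")
        manifest["techniques"]["cavitation"] = {
            "truth": _truth_to_jsonable(truth),
            "entries": entries,
        }

    # --- indentation ------------------------------------------------------
    ind = design.get("indentation")
    if ind and ind.get("n_samples", 0) > 0:
        truth = ind.get("truth", default_truth)
        d = _sub("indentation")
        rng = np.random.default_rng(root.integers(2**31))
        conditions = {"fresh": 1.0}
        if condition_scales:
            conditions.update(condition_scales)
        entries = []
        sample_E = [
            _sample_E(rng, truth) for _ in range(ind["n_samples"])
        ]
        for cond_name, scale in conditions.items():
            for i, e_fresh in enumerate(sample_E):
                sample = f"sample{i:02d}"
                e_cond = e_fresh * scale
                cond_truth = dataclasses.replace(truth, E_true=e_cond)
                for rep in range(ind.get("indents_per_sample", 3)):
                    cseed = int(rng.integers(2**31))
                    curve = gen_force_curve(
                        cond_truth,
                        indenter_radius_a=ind["indenter_radius_m"],
                        sample_thickness_h=ind["sample_thickness_m"],
                        cantilever_stiffness=ind.get(
                            "cantilever_stiffness_n_per_m", math.inf
                        ),
                        max_force=ind.get("max_force_n", 2.0e-3),
                        seed=cseed,
                        sample_id=sample,
                    )
                    stem = f"{cond_name}_{sample}_rep{rep}"
                    tmio.write_force_csv(d / f"{stem}.csv", curve)
                    tmio.write_metadata_yaml(
                        d / f"{stem}.meta.yaml",
                        {
                            "indenter_radius_m": ind["indenter_radius_m"],
                            "sample_thickness_m": ind["sample_thickness_m"],
                            "cantilever_stiffness_n_per_m": float(
                                ind.get("cantilever_stiffness_n_per_m", math.inf)
                            ),
                            "indentation_rate_m_per_s": 20e-6,
                            "sample_id": sample,
                            "condition": cond_name,
                        },
                    )
                    entries.append(
                        {
                            "file": f"indentation/{stem}.csv",
                            "E_true": e_cond,
                            "condition": cond_name,
                            "seed": cseed,
                        }
                    )
                    manifest["files"].append(f"indentation/{stem}.csv")
        manifest["techniques"]["indentation"] = {
            "truth": _truth_to_jsonable(truth),
            "entries": entries,
        }

    # --- saos -------------------------------------------------------------
    sa = design.get("saos")
    if sa and sa.get("n_samples", 0) > 0:
        truth = sa.get("truth", default_truth)
        d = _sub("saos")
        rng = np.random.default_rng(root.integers(2**31))
        entries = []
        for i in range(sa["n_samples"]):
            sample = f"sample{i:02d}"
            a_sample = float(
                truth.powerlaw_A * np.exp(rng.normal(0.0, truth.modulus_noise_fraction))
            )
            sseed = int(rng.integers(2**31))
            sweep = gen_oscillatory_sweep(
                dataclasses.replace(truth, powerlaw_A=a_sample),
                frequencies=sa.get("frequencies_hz"),
                seed=sseed,
                sample_id=sample,
            )
            stem = sample
            tmio.write_sweep_csv(d / f"{stem}.csv", sweep)
            tmio.write_metadata_yaml(
                d / f"{stem}.meta.yaml",
                {"sample_id": sample, "strain_amplitude": 0.005, "temperature_c": 25.0},
            )
            entries.append(
                {"file": f"saos/{stem}.csv", "powerlaw_A_true": a_sample, "seed": sseed}
            )
            manifest["files"].append(f"saos/{stem}.csv")
        manifest["techniques"]["saos"] = {
            "truth": _truth_to_jsonable(truth),
            "entries": entries,
        }

    # --- uniaxial ---------------------------------------------------------
    un = design.get("uniaxial")
    if un and un.get("n_samples", 0) > 0:
        truth = un.get("truth", default_truth)
        d = _sub("uniaxial")
        rng = np.random.default_rng(root.integers(2**31))
        entries = []
        gauge = un.get("gauge_length_m", 27e-3)
        area = un.get("cross_section_area_m2", 20e-6)
        for i in range(un["n_samples"]):
            sample = f"sample{i:02d}"
            toe = float(
                truth.toe_modulus_true
                * np.exp(rng.normal(0.0, truth.modulus_noise_fraction))
            )
            useed = int(rng.integers(2**31))
            curve = gen_stress_strain(
                dataclasses.replace(truth, toe_modulus_true=toe),
                max_strain=un.get("max_strain", 0.4),
                seed=useed,
                gauge_length=gauge,
                cross_section_area=area,
                sample_id=sample,
            )
            stem = sample
            tmio.write_uniaxial_csv(d / f"{stem}.csv", curve)
            tmio.write_metadata_yaml(
                d / f"{stem}.meta.yaml",
                {
                    "gauge_length_m": gauge,
                    "cross_section_area_m2": area,
                    "strain_rate_per_s": 0.01,
                    "sample_id": sample,
                },
            )
            entries.append(
                {"file": f"uniaxial/{stem}.csv", "toe_modulus_true": toe, "seed": useed}
            )
            manifest["files"].append(f"uniaxial/{stem}.csv")
        manifest["techniques"]["uniaxial"] = {
            "truth": _truth_to_jsonable(truth),
            "entries": entries,
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
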