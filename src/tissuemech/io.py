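"""CSV readers/writers for instrument signals, plus YAML metadata and JSONL records.

Column conventions carry explicit unit suffixes::

    pressure trace : time_s, pressure_pa   (pressure_kpa / pressure_psi accepted)
    force curve    : displacement_m, force_n
    SAOS sweep     : frequency_hz, gprime_pa, gdoubleprime_pa
    uniaxial       : strain, stress_pa     (or raw displacement_m, force_n)

Readers are the only place where unit conversion happens; everything
downstream is SI. Missing metadata fields are errors, not defaults, except
the Poisson ratio and the SAOS reference frequency which have protocol
defaults in :class:`~tissuemech.datamodel.AnalysisConfig`.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .datamodel import (
    PSI_TO_PA,
    FormatError,
    ForceCurve,
    ModulusRecord,
    OscillatorySweep,
    PressureTrace,
    StressStrainCurve,
)

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_sweep_csv",
    "write_sweep_csv",
    "read_force_csv",
    "write_force_csv",
    "read_uniaxial_csv",
    "write_uniaxial_csv",
    "read_metadata_yaml",
    "write_metadata_yaml",
    "write_records_jsonl",
    "read_records_jsonl",
]

_PRESSURE_COLUMNS = {"pressure_pa": 1.0, "pressure_kpa": 1e3, "pressure_psi": PSI_TO_PA}


def _load_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    df = pd.read_csv(path)
    if len(df) == 0:
        raise FormatError(f"{path}: file has no data rows")
    return df


def _require(df: pd.DataFrame, columns: Iterable[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _meta(metadata: Mapping, key: str, path) -> float | str:
    if key not in metadata:
        raise FormatError(f"{path}: metadata is missing required field '{key}'")
    return metadata[key]


def read_trace_csv(path: str | Path, metadata: Mapping) -> PressureTrace:
    """Read a cavitation pressure-time trace.

    The pressure column declares its unit by suffix (``pressure_pa``,
    ``pressure_kpa`` or ``pressure_psi``) and is converted to Pa on read.
    Required metadata: ``needle_radius_m``, ``injection_rate_m3_per_s``,
    ``sample_id``.
    """
    df = _load_csv(path)
    _require(df, ["time_s"], path)
    present = [c for c in _PRESSURE_COLUMNS if c in df.columns]
    if not present:
        raise FormatError(
            f"{path}: missing pressure column (one of {sorted(_PRESSURE_COLUMNS)})"
        )
    col = present[0]
    return PressureTrace(
        time=df["time_s"].to_numpy(float),
        pressure=df[col].to_numpy(float) * _PRESSURE_COLUMNS[col],
        needle_radius=float(_meta(metadata, "needle_radius_m", path)),
        injection_rate=float(_meta(metadata, "injection_rate_m3_per_s", path)),
        sample_id=str(_meta(metadata, "sample_id", path)),
        region_id=str(metadata.get("region_id", "")),
    )


def write_trace_csv(path: str | Path, trace: PressureTrace) -> None:
    pd.DataFrame({"time_s": trace.time, "pressure_pa": trace.pressure}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_sweep_csv(path: str | Path, metadata: Mapping | None = None) -> OscillatorySweep:
    """Read an oscillatory frequency sweep (frequency_hz, gprime_pa, gdoubleprime_pa)."""
    metadata = metadata or {}
    df = _load_csv(path)
    _require(df, ["frequency_hz", "gprime_pa", "gdoubleprime_pa"], path)
    return OscillatorySweep(
        frequency=df["frequency_hz"].to_numpy(float),
        storage_modulus_gprime=df["gprime_pa"].to_numpy(float),
        loss_modulus_gdoubleprime=df["gdoubleprime_pa"].to_numpy(float),
        strain_amplitude=float(metadata.get("strain_amplitude", 0.005)),
        temperature=float(metadata.get("temperature_c", 25.0)),
        sample_id=str(metadata.get("sample_id", "")),
    )


def write_sweep_csv(path: str | Path, sweep: OscillatorySweep) -> None:
    pd.DataFrame(
        {
            "frequency_hz": sweep.frequency,
            "gprime_pa": sweep.storage_modulus_gprime,
            "gdoubleprime_pa": sweep.loss_modulus_gdoubleprime,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_force_csv(path: str | Path, metadata: Mapping) -> ForceCurve:
    """Read an indentation force curve (displacement_m, force_n).

    Required metadata: ``indenter_radius_m``, ``sample_thickness_m``,
    ``sample_id``. Optional: ``cantilever_stiffness_n_per_m`` (default rigid)
    and ``indentation_rate_m_per_s`` (default 20 um/s).
    """
    df = _load_csv(path)
    _require(df, ["displacement_m", "force_n"], path)
    stiffness = metadata.get("cantilever_stiffness_n_per_m", math.inf)
    if stiffness in ("inf", "rigid", None):
        stiffness = math.inf
    return ForceCurve(
        displacement=df["displacement_m"].to_numpy(float),
        force=df["force_n"].to_numpy(float),
        indenter_radius_a=float(_meta(metadata, "indenter_radius_m", path)),
        sample_thickness_h=float(_meta(metadata, "sample_thickness_m", path)),
        cantilever_stiffness=float(stiffness),
        indentation_rate=float(metadata.get("indentation_rate_m_per_s", 20e-6)),
        sample_id=str(_meta(metadata, "sample_id", path)),
    )


def write_force_csv(path: str | Path, curve: ForceCurve) -> None:
    pd.DataFrame(
        {"displacement_m": curve.displacement, "force_n": curve.force}
    ).to_csv(path, index=False, float_format="%.12g")


def read_uniaxial_csv(path: str | Path, metadata: Mapping) -> StressStrainCurve:
    """Read a uniaxial tension record.

    Accepts either engineering columns (``strain``, ``stress_pa``) or raw
    instrument columns (``displacement_m``, ``force_n``) which are converted
    to engineering strain/stress using ``gauge_length_m`` and
    ``cross_section_area_m2`` from the metadata.
    """
    df = _load_csv(path)
    gauge = float(_meta(metadata, "gauge_length_m", path))
    area = float(_meta(metadata, "cross_section_area_m2", path))
    if "strain" in df.columns and "stress_pa" in df.columns:
        strain = df["strain"].to_numpy(float)
        stress = df["stress_pa"].to_numpy(float)
    elif "displacement_m" in df.columns and "force_n" in df.columns:
        strain = df["displacement_m"].to_numpy(float) / gauge
        stress = df["force_n"].to_numpy(float) / area
    else:
        raise FormatError(
            f"{path}: need columns (strain, stress_pa) or (displacement_m, force_n)"
        )
    return StressStrainCurve(
        strain=strain,
        stress=stress,
        gauge_length=gauge,
        cross_section_area=area,
        strain_rate=float(_meta(metadata, "strain_rate_per_s", path)),
        sample_id=str(_meta(metadata, "sample_id", path)),
    )


def write_uniaxial_csv(path: str | Path, curve: StressStrainCurve) -> None:
    pd.DataFrame({"strain": curve.strain, "stress_pa": curve.stress}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_metadata_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"metadata file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: metadata YAML must be a mapping")
    return data


def write_metadata_yaml(path: str | Path, metadata: Mapping) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(metadata), fh, sort_keys=True)


def write_records_jsonl(path: str | Path, records: Iterable[ModulusRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_dict()) + "\n")


def read_records_jsonl(path: str | Path) -> list[ModulusRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(ModulusRecord.from_dict(json.loads(line)))
    return records
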