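"""End-to-end orchestration: study directory -> records -> summary -> comparisons.

Consumes the directory layout written by :func:`tissuemech.synthetic.gen_study`
(or hand-converted instrument exports in the same layout): per-technique
subfolders of CSV signals with ``.meta.yaml`` sidecars. Produces one
ModulusRecord per sample/technique, a rate-adjusted summary table, pairwise
technique comparisons and a reproducible run manifest. A failure in one
file or stage is logged and reported; the remaining stages continue.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cavitation as cav
from . import crossplatform as xp
from . import indentation as ind
from . import io as tmio
from . import saos as sa
from . import uniaxial as un
from .datamodel import (
    AnalysisConfig,
    Condition,
    ModulusRecord,
    Technique,
    TissueMechError,
)

logger = logging.getLogger("tissuemech")

__all__ = ["RunManifest", "RunReport", "run_end_to_end"]


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int
    package_version: str
    input_files: list[str] = field(default_factory=list)
    output_files: list[str] = field(default_factory=list)
    started_at: float = 0.0
    finished_at: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    records: list[ModulusRecord]
    summary: pd.DataFrame
    summary_adjusted: pd.DataFrame
    comparisons: list[xp.ComparisonResult]
    errors: list[str]
    manifest: RunManifest


def _config_hash(config: AnalysisConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _meta_for(path: Path) -> dict:
    return tmio.read_metadata_yaml(path.with_name(path.stem + ".meta.yaml"))


def _collect_cavitation(study: Path, config: AnalysisConfig, errors: list[str]):
    records = []
    d = study / "cavitation"
    if not d.is_dir():
        return records
    by_region: dict[str, list] = defaultdict(list)
    for csv in sorted(d.glob("*.csv")):
        try:
            meta = _meta_for(csv)
            trace = tmio.read_trace_csv(csv, meta)
            by_region[trace.region_id or trace.sample_id].append(trace)
        except TissueMechError as exc:
            errors.append(f"cavitation/{csv.name}: {exc}")
    for region, traces in sorted(by_region.items()):
        try:
            fit, events = cav.analyze_traces(traces, config)
            rate = cav.cavitation_strain_rate(traces[0])
            records.append(
                ModulusRecord(
                    technique=Technique.CAVITATION,
                    sample_id=region,
                    region_id=region,
                    young_modulus=fit.E_eff,
                    strain_rate=float(rate),
                )
            )
        except TissueMechError as exc:
            errors.append(f"cavitation region {region}: {exc}")
    return records


def _collect_indentation(study: Path, config: AnalysisConfig, errors: list[str]):
    records = []
    d = study / "indentation"
    if not d.is_dir():
        return records
    # per sample & condition: mean modulus over replicate indents
    acc: dict[tuple[str, str], list[float]] = defaultdict(list)
    rates: dict[tuple[str, str], float] = {}
    for csv in sorted(d.glob("*.csv")):
        try:
            meta = _meta_for(csv)
            curve = tmio.read_force_csv(csv, meta)
            result = ind.analyze_curve(curve, config)
            key = (curve.sample_id, str(meta.get("condition", "fresh")))
            acc[key].append(result.young_modulus)
            rates[key] = ind.indentation_strain_rate(
                curve.indentation_rate, curve.sample_thickness_h
            )
        except TissueMechError as exc:
            errors.append(f"indentation/{csv.name}: {exc}")
    for (sample, cond), values in sorted(acc.items()):
        records.append(
            ModulusRecord(
                technique=Technique.INDENTATION,
                sample_id=sample,
                young_modulus=float(np.mean(values)),
                strain_rate=rates[(sample, cond)],
                condition=Condition(cond),
            )
        )
    return records


def _collect_saos(study: Path, config: AnalysisConfig, errors: list[str]):
    records = []
    fits = []
    d = study / "saos"
    if not d.is_dir():
        return records, fits
    for csv in sorted(d.glob("*.csv")):
        try:
            meta = _meta_for(csv)
            sweep = tmio.read_sweep_csv(csv, meta)
            result = sa.analyze_sweep(sweep, config)
            fits.append(result.powerlaw)
            records.append(
                ModulusRecord(
                    technique=Technique.SAOS,
                    sample_id=sweep.sample_id,
                    young_modulus=result.young_modulus,
                    strain_rate=config.reference_frequency,
                )
            )
        except TissueMechError as exc:
            errors.append(f"saos/{csv.name}: {exc}")
    return records, fits


def _collect_uniaxial(study: Path, config: AnalysisConfig, errors: list[str]):
    records = []
    d = study / "uniaxial"
    if not d.is_dir():
        return records
    for csv in sorted(d.glob("*.csv")):
        try:
            meta = _meta_for(csv)
            curve = tmio.read_uniaxial_csv(csv, meta)
            result = un.fit_bilinear(curve, breakpoint_margin=config.breakpoint_margin)
            records.append(
                ModulusRecord(
                    technique=Technique.UNIAXIAL_TOE,
                    sample_id=curve.sample_id,
                    young_modulus=result.toe_modulus,
                    strain_rate=curve.strain_rate,
                )
            )
            if result.identifiable:
                records.append(
                    ModulusRecord(
                        technique=Technique.UNIAXIAL_LINEAR,
                        sample_id=curve.sample_id,
                        young_modulus=result.linear_modulus,
                        strain_rate=curve.strain_rate,
                    )
                )
        except TissueMechError as exc:
            errors.append(f"uniaxial/{csv.name}: {exc}")
    return records


def run_end_to_end(
    config: AnalysisConfig,
    study_dir: str | Path,
    out_dir: str | Path | None = None,
    command: str = "run_end_to_end",
) -> RunReport:
    """Analyze every technique subfolder of a study directory.

    Expects at least one of ``cavitation/``, ``indentation/``, ``saos/``,
    ``uniaxial/`` under ``study_dir``. Writes (when ``out_dir`` is given)
    ``records.jsonl``, ``summary.csv``, ``summary_adjusted.csv``,
    ``comparisons.json`` and ``run_manifest.json``.
    """
    study = Path(study_dir)
    expected = ["cavitation", "indentation", "saos", "uniaxial"]
    present = [name for name in expected if (study / name).is_dir()]
    if not present:
        raise TissueMechError(
            f"study directory {study} contains none of the technique "
            f"subfolders {expected}"
        )
    manifest = RunManifest(
        command=command,
        config_hash=_config_hash(config),
        seed=config.random_seed,
        package_version=_package_version(),
        started_at=time.time(),
    )
    errors: list[str] = []
    t0 = time.perf_counter()
    records = _collect_cavitation(study, config, errors)
    logger.info("cavitation stage: %d records, %.2fs", len(records), time.perf_counter() - t0)

    t0 = time.perf_counter()
    ind_records = _collect_indentation(study, config, errors)
    records += ind_records
    logger.info("indentation stage: %d records, %.2fs", len(ind_records), time.perf_counter() - t0)

    t0 = time.perf_counter()
    saos_records, powerlaw_fits = _collect_saos(study, config, errors)
    records += saos_records
    logger.info("saos stage: %d records, %.2fs", len(saos_records), time.perf_counter() - t0)

    t0 = time.perf_counter()
    un_records = _collect_uniaxial(study, config, errors)
    records += un_records
    logger.info("uniaxial stage: %d records, %.2fs", len(un_records), time.perf_counter() - t0)

    for err in errors:
        logger.warning("stage error: %s", err)

    # rate adjustment: mean SAOS beta when available, else the 0.11 default
    if powerlaw_fits:
        beta = float(np.mean([f.beta for f in powerlaw_fits]))
    else:
        beta = config.powerlaw_beta_default
    records = xp.rate_adjust_records(
        records, reference_rate=config.reference_frequency, beta=beta
    )

    fresh = [r for r in records if r.condition == Condition.FRESH]
    summary = xp.summarize_by_technique(fresh)
    summary_adj = xp.summarize_by_technique(fresh, adjusted=True)

    comparisons = []
    groups = defaultdict(list)
    for rec in fresh:
        groups[rec.technique.value].append(rec.young_modulus)
    names = sorted(groups)
    for i, name_a in enumerate(names):
        for name_b in names[i + 1 :]:
            if len(groups[name_a]) >= 2 and len(groups[name_b]) >= 2:
                comparisons.append(
                    xp.compare_groups(
                        groups[name_a],
                        groups[name_b],
                        paired=False,
                        label_a=name_a,
                        label_b=name_b,
                    )
                )

    manifest.input_files = sorted(
        str(p.relative_to(study)) for p in study.rglob("*.csv")
    )
    manifest.finished_at = time.time()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tmio.write_records_jsonl(out / "records.jsonl", records)
        summary.to_csv(out / "summary.csv", index=False)
        summary_adj.to_csv(out / "summary_adjusted.csv", index=False)
        with open(out / "comparisons.json", "w") as fh:
            json.dump([c.to_dict() for c in comparisons], fh, indent=1)
        manifest.output_files = [
            "records.jsonl",
            "summary.csv",
            "summary_adjusted.csv",
            "comparisons.json",
        ]
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=1)
        if errors:
            with open(out / "errors.log", "w") as fh:
                fh.write("\n".join(errors) + "\n")

    return RunReport(
        records=records,
        summary=summary,
        summary_adjusted=summary_adj,
        comparisons=comparisons,
        errors=errors,
        manifest=manifest,
    )


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("tissuemech")
    except Exception:  # pragma: no cover - not installed
        return "unknown"
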