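"""Aggregate moduli across techniques, normalize for strain rate, compare groups.

The four techniques probe the tissue at different characteristic strain
rates (cavitation ~0.028, indentation ~0.04, uniaxial ~0.01, SAOS 0.1 1/s).
Because soft tissue is power-law viscoelastic (|G*| ~ omega^beta, beta ~
0.11), a modulus measured at rate r scales to a reference rate r_ref as
E_adj = E * (r_ref / r)^beta. Group comparisons use two-tailed Student's
t-tests (pooled variance unpaired, difference-based paired), mirroring the
study's statistics; no multiple-testing correction by default, with a
Bonferroni option.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    DomainError,
    InsufficientDataError,
    ModulusRecord,
)
from .saos import PowerLawFit

__all__ = [
    "DEFAULT_TECHNIQUE_RATES",
    "ComparisonResult",
    "rate_adjust_modulus",
    "rate_adjust_records",
    "summarize_by_technique",
    "compare_groups",
    "freeze_thaw_report",
]

#: Protocol strain rates (1/s) used when a record's rate is not computable
#: from metadata: cavitation from the air injection rate, indentation from
#: 20 um/s over ~0.5 mm, uniaxial from 1%/s, SAOS at the reference frequency.
DEFAULT_TECHNIQUE_RATES = {
    "cavitation": 0.028,
    "indentation": 0.04,
    "saos": 0.1,
    "uniaxial_toe": 0.01,
    "uniaxial_linear": 0.01,
}


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant_at_0_05: bool
    paired: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError(f"p_value out of [0,1]: {self.p_value}")
        if self.significant_at_0_05 != (self.p_value < 0.05):
            raise DomainError("significance flag inconsistent with p-value")

    def to_dict(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "mean_a_pa": self.mean_a,
            "sd_a_pa": self.sd_a,
            "n_a": self.n_a,
            "mean_b_pa": self.mean_b,
            "sd_b_pa": self.sd_b,
            "n_b": self.n_b,
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "significant_at_0_05": self.significant_at_0_05,
            "paired": self.paired,
        }


def rate_adjust_modulus(
    E: float, measured_rate: float, reference_rate: float, beta: float = 0.11
) -> float:
    """Scale a modulus from its measured strain rate to a reference rate.

    E_adj = E * (reference_rate / measured_rate)^beta. The identity holds at
    equal rates or beta = 0, and adjusting back is the exact inverse.
    """
    if not (measured_rate > 0 and reference_rate > 0):
        raise DomainError(
            f"rates must be > 0 (measured={measured_rate}, reference={reference_rate})"
        )
    return E * (reference_rate / measured_rate) ** beta


def rate_adjust_records(
    records: Sequence[ModulusRecord],
    reference_rate: float = 0.1,
    powerlaw: PowerLawFit | None = None,
    beta: float = 0.11,
) -> list[ModulusRecord]:
    """Fill ``rate_adjusted_modulus`` on every record.

    ``beta`` defaults to the SAOS-derived 0.11 unless a fitted
    :class:`~tissuemech.saos.PowerLawFit` is supplied. A record with a
    non-positive stored rate falls back to its technique's protocol rate.
    """
    if powerlaw is not None:
        beta = powerlaw.beta
    out = []
    for rec in records:
        rate = rec.strain_rate
        if not rate > 0:
            rate = DEFAULT_TECHNIQUE_RATES[rec.technique.value]
        out.append(
            dataclasses.replace(
                rec,
                rate_adjusted_modulus=rate_adjust_modulus(
                    rec.young_modulus, rate, reference_rate, beta
                ),
            )
        )
    return out


def summarize_by_technique(
    records: Sequence[ModulusRecord], adjusted: bool = False
) -> pd.DataFrame:
    """Per-technique n, mean, SD (n-1 denominator) and SEM in Pa.

    A single-record group reports sd = 0 and is flagged ``n_is_1``.
    """
    if len(records) == 0:
        raise InsufficientDataError("no records to summarize")
    rows = []
    for rec in records:
        value = rec.rate_adjusted_modulus if adjusted else rec.young_modulus
        if value is None:
            raise DomainError(
                "rate_adjusted_modulus requested but missing; run rate_adjust_records"
            )
        rows.append({"technique": rec.technique.value, "modulus": value})
    df = pd.DataFrame(rows)
    out = []
    for tech, group in df.groupby("technique", sort=True):
        vals = group["modulus"].to_numpy()
        n = len(vals)
        sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        out.append(
            {
                "technique": tech,
                "n": n,
                "mean_pa": float(np.mean(vals)),
                "sd_pa": sd,
                "sem_pa": sd / np.sqrt(n) if n > 1 else 0.0,
                "n_is_1": n == 1,
            }
        )
    return pd.DataFrame(out)


def _two_tailed_p(t: float, df: float) -> float:
    return float(2.0 * stats.t.sf(abs(t), df))


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    label_a: str = "a",
    label_b: str = "b",
) -> ComparisonResult:
    """Two-tailed Student's t-test between two groups of moduli.

    Unpaired uses the pooled-variance statistic with n_a + n_b - 2 degrees
    of freedom; paired tests the mean within-pair difference with n - 1
    degrees of freedom. Identical groups give t = 0, p = 1 (including the
    degenerate paired case where every difference is exactly zero).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need >= 2 values per group (got {len(a)}, {len(b)})"
        )
    mean_a, mean_b = float(np.mean(a)), float(np.mean(b))
    sd_a = float(np.std(a, ddof=1))
    sd_b = float(np.std(b, ddof=1))
    if paired:
        if len(a) != len(b):
            raise InsufficientDataError("paired comparison requires equal lengths")
        d = a - b
        n = len(d)
        df = n - 1.0
        sd_d = float(np.std(d, ddof=1))
        md = float(np.mean(d))
        if sd_d == 0.0:
            t = 0.0 if md == 0.0 else np.sign(md) * np.inf
            p = 1.0 if md == 0.0 else 0.0
        else:
            t = md / (sd_d / np.sqrt(n))
            p = _two_tailed_p(t, df)
    else:
        n_a, n_b = len(a), len(b)
        df = n_a + n_b - 2.0
        pooled_var = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
        se = np.sqrt(pooled_var * (1.0 / n_a + 1.0 / n_b))
        if se == 0.0:
            t = 0.0 if mean_a == mean_b else np.sign(mean_a - mean_b) * np.inf
            p = 1.0 if mean_a == mean_b else 0.0
        else:
            t = float((mean_a - mean_b) / se)
            p = _two_tailed_p(t, df)
    return ComparisonResult(
        group_a=label_a,
        group_b=label_b,
        mean_a=mean_a,
        sd_a=sd_a,
        mean_b=mean_b,
        sd_b=sd_b,
        n_a=len(a),
        n_b=len(b),
        t_statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=float(p),
        significant_at_0_05=bool(p < 0.05),
        paired=paired,
    )


def freeze_thaw_report(
    fresh: Sequence[ModulusRecord],
    frozen: Mapping[str, Sequence[ModulusRecord]],
    bonferroni: bool = False,
) -> tuple[list[ComparisonResult], pd.DataFrame]:
    """Paired fresh-vs-frozen comparisons per freezing method.

    Records are paired by ``sample_id`` (the same physical sample measured
    fresh, then after freezing); per-sample means are used when a sample has
    replicate records. Returns the per-method comparison list and a
    per-sample delta table (frozen - fresh, Pa). With ``bonferroni`` the
    significance threshold is divided by the number of methods (p-values are
    reported unadjusted; only the flag changes).
    """
    if not frozen:
        raise InsufficientDataError("no frozen groups supplied")

    def _by_sample(records: Sequence[ModulusRecord]) -> dict[str, float]:
        acc: dict[str, list[float]] = {}
        for rec in records:
            acc.setdefault(rec.sample_id, []).append(rec.young_modulus)
        return {k: float(np.mean(v)) for k, v in acc.items()}

    fresh_means = _by_sample(fresh)
    results = []
    delta_rows = []
    n_methods = len(frozen)
    for method, records in frozen.items():
        if len(records) == 0:
            raise InsufficientDataError(f"frozen group '{method}' is empty")
        froz_means = _by_sample(records)
        common = sorted(set(fresh_means) & set(froz_means))
        if len(common) < 2:
            raise InsufficientDataError(
                f"frozen group '{method}': fewer than 2 paired samples"
            )
        a = [fresh_means[s] for s in common]
        b = [froz_means[s] for s in common]
        res = compare_groups(a, b, paired=True, label_a="fresh", label_b=method)
        for s in common:
            row = {
                "method": method,
                "sample_id": s,
                "fresh_pa": fresh_means[s],
                "frozen_pa": froz_means[s],
                "delta_pa": froz_means[s] - fresh_means[s],
            }
            if bonferroni:
                # raw p-values are reported; only the verdict is corrected
                row["significant_bonferroni"] = res.p_value < 0.05 / n_methods
            delta_rows.append(row)
        results.append(res)
    return results, pd.DataFrame(delta_rows)
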