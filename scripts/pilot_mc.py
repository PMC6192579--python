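"""Pilot oracle run: establish Monte-Carlo recovery tolerances.

Run once with the pilot seed (20250921, distinct from the test-suite seed
base 1000); the resulting tolerances (1.5 x the pilot 95th percentile of
|relative error|, rounded up to 2 significant digits) are frozen into
tests/fixtures/mc_tolerances.json and not revisited.
"""

import json
import math
import numpy as np

from tissuemech import cavitation as cav
from tissuemech import indentation as ind
from tissuemech import saos, synthetic as syn, uniaxial

PILOT_SEED = 20250921
N = 100


def rel(x, truth):
    return abs(x / truth - 1.0)


def pilot():
    rng = np.random.default_rng(PILOT_SEED)
    out = {}

    truth = syn.MaterialGroundTruth(E_true=6.1e3)
    errs = []
    for _ in range(N):
        traces = [
            syn.gen_cavitation_trace(truth, r, seed=int(rng.integers(2**31)))
            for r in syn.LUNG_NEEDLE_RADII_M
            for _ in range(3)
        ]
        fit, _ = cav.analyze_traces(traces)
        errs.append(rel(fit.E_eff, truth.E_true))
    out["cavitation_E_relerr"] = errs

    truth = syn.MaterialGroundTruth(E_true=1.4e3)
    errs = []
    for _ in range(N):
        curve = syn.gen_force_curve(
            truth, 0.5e-3, 2e-3, 10.0, 2e-3, seed=int(rng.integers(2**31))
        )
        errs.append(rel(ind.analyze_curve(curve).young_modulus, truth.E_true))
    out["indentation_E_relerr"] = errs

    truth = syn.MaterialGroundTruth(powerlaw_A=1496.9, powerlaw_beta=0.11)
    E_true = 2 * truth.powerlaw_A * 0.1**0.11 * 1.42
    errs_E, errs_b = [], []
    for _ in range(N):
        sweep = syn.gen_oscillatory_sweep(truth, seed=int(rng.integers(2**31)))
        res = saos.analyze_sweep(sweep)
        errs_E.append(rel(res.young_modulus, E_true))
        errs_b.append(abs(res.powerlaw.beta - 0.11))
    out["saos_E_relerr"] = errs_E
    out["saos_beta_abserr"] = errs_b

    truth = syn.MaterialGroundTruth(toe_modulus_true=3.4e3)
    errs = []
    for _ in range(N):
        curve = syn.gen_stress_strain(truth, seed=int(rng.integers(2**31)))
        errs.append(rel(uniaxial.fit_bilinear(curve).toe_modulus, truth.toe_modulus_true))
    out["uniaxial_toe_relerr"] = errs
    return out


def round_up_2sig(x):
    if x == 0:
        return 0.0
    e = math.floor(math.log10(x))
    m = math.ceil(x / 10 ** (e - 1)) * 10 ** (e - 1)
    return float(f"{m:.2g}")


if __name__ == "__main__":
    res = pilot()
    tol = {}
    for key, errs in res.items():
        p95 = float(np.percentile(errs, 95))
        tol[key.replace("err", "err_tol")] = round_up_2sig(1.5 * p95)
        print(key, "median", round(float(np.median(errs)), 5), "p95", round(p95, 5))
    payload = {
        "pilot_seed": PILOT_SEED,
        "n_replicates": N,
        "rule": "1.5 * pilot p95 of |error|, rounded up to 2 significant digits",
        "tolerances": tol,
    }
    print(json.dumps(payload, indent=1))
    with open("tests/fixtures/mc_tolerances.json", "w") as fh:
        json.dump(payload, fh, indent=1)
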