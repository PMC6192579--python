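"""Generator correctness: peak values, determinism, forward/inverse consistency."""

import dataclasses
import math
from pathlib import Path

import numpy as np
import pytest

from tissuemech import cavitation as cav
from tissuemech import indentation as ind
from tissuemech import synthetic as syn
from tissuemech.datamodel import DomainError


class TestCavitationTrace:
    def test_noiseless_peak_matches_critical_pressure_relation(self, clean_truth):
        # Pc = 1.05*5000 + 2.1*0.02/5.97e-4 = 5320.35... Pa
        trace = syn.gen_cavitation_trace(clean_truth, 0.597e-3, seed=1)
        expected = 1.05 * 5000 + 2.1 * 0.02 / 0.597e-3
        assert trace.pressure.max() == pytest.approx(expected, rel=1e-12)

    def test_modulus_coefficient_alone_sets_peak(self, clean_truth):
        truth = dataclasses.replace(clean_truth, E_true=1e3, surface_tension_true=0.0)
        trace = syn.gen_cavitation_trace(truth, 1e-3, seed=0)
        assert trace.pressure.max() == pytest.approx(1050.0, rel=1e-12)

    def test_seeded_determinism(self, clean_truth):
        truth = dataclasses.replace(clean_truth, pressure_noise_fraction=0.02)
        a = syn.gen_cavitation_trace(truth, 0.5e-3, seed=7)
        b = syn.gen_cavitation_trace(truth, 0.5e-3, seed=7)
        np.testing.assert_array_equal(a.pressure, b.pressure)
        c = syn.gen_cavitation_trace(truth, 0.5e-3, seed=8)
        assert not np.array_equal(a.pressure, c.pressure)

    def test_nonpositive_radius_rejected(self, clean_truth):
        with pytest.raises(DomainError):
            syn.gen_cavitation_trace(clean_truth, 0.0)

    def test_ramp_monotone_then_drop(self, clean_truth):
        trace = syn.gen_cavitation_trace(clean_truth, 0.5e-3, seed=0)
        peak = int(np.argmax(trace.pressure))
        assert np.all(np.diff(trace.pressure[: peak + 1]) > 0)
        assert trace.pressure[peak + 1] == pytest.approx(
            0.2 * trace.pressure[peak], rel=1e-12
        )


class TestForceCurve:
    def test_rigid_cantilever_slope_is_inverted_compliance(self, clean_truth):
        truth = dataclasses.replace(clean_truth, E_true=2e3)
        curve = syn.gen_force_curve(truth, 0.5e-3, 2e-3, math.inf, 2e-3, seed=0)
        C_expected = ind.compliance_from_modulus(2e3, 0.5e-3, 2e-3, 0.42)
        post = curve.force > 1e-12
        slope = np.polyfit(curve.force[post], curve.displacement[post], 1)[0]
        assert slope == pytest.approx(C_expected, rel=1e-10)

    def test_finite_cantilever_adds_series_compliance(self, clean_truth):
        truth = dataclasses.replace(clean_truth, E_true=2e3)
        k = 10.0
        curve = syn.gen_force_curve(truth, 0.5e-3, 2e-3, k, 2e-3, seed=0)
        C_expected = ind.compliance_from_modulus(2e3, 0.5e-3, 2e-3, 0.42)
        post = curve.force > 1e-12
        slope = np.polyfit(curve.force[post], curve.displacement[post], 1)[0]
        assert slope == pytest.approx(C_expected + 1.0 / k, rel=1e-10)

    def test_contact_offset_sets_first_force_rise(self, clean_truth):
        curve = syn.gen_force_curve(
            clean_truth, 0.5e-3, 2e-3, math.inf, 2e-3, seed=0, contact_offset=0.3e-3
        )
        # first positive force is one force step after contact, i.e. within
        # one post-contact displacement increment of the offset
        first_rise = int(np.flatnonzero(curve.force > 0)[0])
        assert curve.displacement[first_rise] == pytest.approx(0.3e-3, abs=2e-6)


class TestOscillatorySweep:
    def test_zero_exponent_gives_flat_sweep(self, clean_truth):
        truth = dataclasses.replace(clean_truth, powerlaw_A=3e3, powerlaw_beta=0.0)
        sweep = syn.gen_oscillatory_sweep(truth, seed=0)
        mag = np.hypot(sweep.storage_modulus_gprime, sweep.loss_modulus_gdoubleprime)
        np.testing.assert_allclose(mag, 3e3, rtol=1e-12)

    def test_zero_loss_tangent_is_purely_elastic(self, clean_truth):
        truth = dataclasses.replace(clean_truth, loss_tangent=0.0, powerlaw_A=3e3)
        sweep = syn.gen_oscillatory_sweep(truth, seed=0)
        np.testing.assert_array_equal(sweep.loss_modulus_gdoubleprime, 0.0)
        mag = np.hypot(sweep.storage_modulus_gprime, sweep.loss_modulus_gdoubleprime)
        np.testing.assert_allclose(mag, sweep.storage_modulus_gprime)

    def test_magnitude_at_unit_frequency_equals_A(self, clean_truth):
        truth = dataclasses.replace(clean_truth, powerlaw_A=3e3, powerlaw_beta=0.11)
        sweep = syn.gen_oscillatory_sweep(truth, frequencies=[0.5, 0.75, 1.0], seed=0)
        mag = np.hypot(
            sweep.storage_modulus_gprime[-1], sweep.loss_modulus_gdoubleprime[-1]
        )
        assert mag == pytest.approx(3e3, rel=1e-12)

    def test_empty_frequency_list_rejected(self, clean_truth):
        with pytest.raises(DomainError):
            syn.gen_oscillatory_sweep(clean_truth, frequencies=[])


class TestStressStrain:
    def test_stress_at_transition(self, clean_truth):
        truth = dataclasses.replace(
            clean_truth, toe_modulus_true=3.4e3, linear_modulus_true=30e3,
            transition_strain_true=0.15,
        )
        curve = syn.gen_stress_strain(truth, max_strain=0.45, n_points=301, seed=0)
        i = int(np.argmin(np.abs(curve.strain - 0.15)))
        assert curve.strain[i] == pytest.approx(0.15, abs=1e-12)
        assert curve.stress[i] == pytest.approx(0.15 * 3400, rel=1e-12)

    def test_equal_slopes_is_exactly_linear(self, clean_truth):
        truth = dataclasses.replace(
            clean_truth, toe_modulus_true=5e3, linear_modulus_true=5e3
        )
        curve = syn.gen_stress_strain(truth, seed=0)
        np.testing.assert_allclose(curve.stress, 5e3 * curve.strain, rtol=1e-12)


class TestGenStudy:
    def test_file_counts_and_manifest(self, tmp_path, clean_truth):
        design = {
            "cavitation": {
                "truth": clean_truth,
                "n_regions": 1,
                "needle_radii_m": list(syn.LUNG_NEEDLE_RADII_M),
                "traces_per_radius": 3,
            }
        }
        manifest = syn.gen_study(design, tmp_path, seed=0)
        files = list((tmp_path / "cavitation").glob("*.csv"))
        assert len(files) == 12  # 4 radii x 3 replicates
        assert len(manifest["files"]) == 12
        assert (tmp_path / "manifest.json").exists()

    def test_zero_replicates_omits_technique(self, tmp_path, clean_truth):
        design = {
            "cavitation": {"truth": clean_truth, "n_regions": 0, "needle_radii_m": []},
            "uniaxial": {"truth": clean_truth, "n_samples": 2},
        }
        manifest = syn.gen_study(design, tmp_path, seed=0)
        assert not (tmp_path / "cavitation").exists()
        assert "cavitation" not in manifest["techniques"]
        assert len(list((tmp_path / "uniaxial").glob("*.csv"))) == 2

    def test_same_seed_byte_identical_tree(self, tmp_path):
        design = syn.preset_design("hydrogel")
        a, b = tmp_path / "a", tmp_path / "b"
        syn.gen_study(design, a, seed=11)
        syn.gen_study(design, b, seed=11)
        files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
        assert files_a == files_b
        for rel in files_a:
            assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel


class TestForwardInverseIdentity:
    """Zero-noise generator output re-analyzed recovers truth to 1e-8 relative."""

    def test_cavitation(self, clean_truth):
        events = [
            cav.detect_cavitation_event(
                syn.gen_cavitation_trace(clean_truth, r, seed=0)
            )
            for r in syn.LUNG_NEEDLE_RADII_M
        ]
        fit = cav.fit_cavitation_series(events)
        assert fit.E_eff == pytest.approx(clean_truth.E_true, rel=1e-8)
        assert fit.surface_tension == pytest.approx(
            clean_truth.surface_tension_true, rel=1e-8
        )

    def test_indentation(self, clean_truth):
        truth = dataclasses.replace(clean_truth, E_true=2e3)
        curve = syn.gen_force_curve(truth, 0.5e-3, 2e-3, 10.0, 2e-3, seed=0)
        result = ind.analyze_curve(curve)
        assert result.young_modulus == pytest.approx(2e3, rel=1e-8)

    def test_saos(self, clean_truth):
        from tissuemech import saos

        truth = dataclasses.replace(
            clean_truth, powerlaw_A=3e3, powerlaw_beta=0.11
        )
        sweep = syn.gen_oscillatory_sweep(truth, seed=0)
        fit = saos.fit_power_law(sweep)
        assert fit.A == pytest.approx(3e3, rel=1e-8)
        assert fit.beta == pytest.approx(0.11, rel=1e-8)

    def test_uniaxial(self, clean_truth):
        from tissuemech import uniaxial

        truth = dataclasses.replace(
            clean_truth, toe_modulus_true=3.4e3, linear_modulus_true=30e3,
            transition_strain_true=0.15,
        )
        curve = syn.gen_stress_strain(truth, seed=0)
        result = uniaxial.fit_bilinear(curve)
        assert result.toe_modulus == pytest.approx(3.4e3, rel=1e-8)
        assert result.linear_modulus == pytest.approx(30e3, rel=1e-8)
        assert result.transition_strain == pytest.approx(0.15, rel=1e-6)
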