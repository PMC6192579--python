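"""Cavitation analysis: forward relation, filtering, event detection, 1/r fit."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuemech import cavitation as cav
from tissuemech import synthetic as syn
from tissuemech.datamodel import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
    PressureTrace,
)


def _make_trace(pressure, dt=0.01, radius=0.5e-3):
    t = np.arange(len(pressure)) * dt
    return PressureTrace(t, np.asarray(pressure, float), radius, 8.333e-8, "t")


class TestPredict:
    def test_modulus_coefficient(self):
        assert cav.predict_critical_pressure(1000.0, 0.0, 0.3e-3) == pytest.approx(1050.0)

    def test_zero_material_zero_pressure(self):
        assert cav.predict_critical_pressure(0.0, 0.0, 1e-3) == 0.0

    def test_hand_evaluated_combination(self):
        got = cav.predict_critical_pressure(5000.0, 0.02, 5.97e-4)
        assert got == pytest.approx(5250 + 2.1 * 0.02 / 5.97e-4, rel=1e-12)
        assert got == pytest.approx(5320.35, abs=0.01)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(DomainError):
            cav.predict_critical_pressure(1000.0, 0.02, 0.0)

    def test_surface_tension_term_decreases_with_radius(self):
        radii = np.array([0.1e-3, 0.2e-3, 0.4e-3, 0.8e-3])
        pcs = [cav.predict_critical_pressure(5e3, 0.02, r) for r in radii]
        assert np.all(np.diff(pcs) < 0)
        flat = [cav.predict_critical_pressure(5e3, 0.0, r) for r in radii]
        assert len(set(flat)) == 1


class TestFilter:
    def test_constant_trace_unchanged(self):
        trace = _make_trace(np.full(1000, 2000.0))
        out = cav.filter_trace(trace)
        np.testing.assert_allclose(out.pressure, 2000.0, atol=1e-9)
        assert out.filtered

    def test_high_frequency_sinusoid_attenuated(self):
        # 40 Hz tone with 10 Hz cutoff at fs=100 Hz: amplitude should drop >90%
        t = np.arange(2000) * 0.01
        trace = _make_trace(1000.0 + 500.0 * np.sin(2 * np.pi * 40 * t))
        out = cav.filter_trace(trace, order=2, cutoff=10.0)
        inner = slice(200, -200)  # avoid filtfilt edge transients
        assert np.abs(out.pressure[inner] - 1000.0).max() < 0.1 * 500.0

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(3)
        trace = _make_trace(1000.0 + rng.normal(0, 100, 2000))
        out = cav.filter_trace(trace)
        assert np.var(out.pressure) < np.var(trace.pressure)

    def test_cutoff_above_nyquist_rejected(self):
        trace = _make_trace(np.full(100, 1.0))  # fs = 100 Hz, Nyquist 50
        with pytest.raises(ConfigurationError):
            cav.filter_trace(trace, cutoff=60.0)


class TestDetect:
    def test_constructed_ramp_and_drop(self):
        # ramp to 6 kPa over 10 s then sudden drop to 1 kPa
        up = np.linspace(0, 6000, 1000)
        down = np.full(200, 1000.0)
        event = cav.detect_cavitation_event(_make_trace(np.concatenate([up, down])))
        assert event.critical_pressure == pytest.approx(6000.0)
        assert event.event_time == pytest.approx(9.99, abs=0.02)

    def test_strictly_increasing_trace_has_no_event(self):
        with pytest.raises(cav.NoCavitationEventError):
            cav.detect_cavitation_event(_make_trace(np.linspace(0, 5000, 500)))

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        up = np.linspace(0, 6000, 1000) + rng.normal(0, 60, 1000)
        down = np.full(200, 1000.0) + rng.normal(0, 60, 200)
        p = np.concatenate([up, down])
        e0 = cav.detect_cavitation_event(_make_trace(p))
        e1 = cav.detect_cavitation_event(_make_trace(p + 50_000.0))
        assert e1.critical_pressure - e0.critical_pressure == pytest.approx(50_000.0)
        assert e1.event_time == e0.event_time

    def test_noisy_generator_peak_within_three_sd(self, clean_truth):
        truth = dataclasses.replace(clean_truth, pressure_noise_fraction=0.02)
        expected = cav.predict_critical_pressure(5000.0, 0.02, 0.597e-3)
        trace = syn.gen_cavitation_trace(truth, 0.597e-3, seed=7)
        event = cav.detect_cavitation_event(
            cav.filter_trace(trace), peak_source=trace, peak_estimator="median-window"
        )
        assert abs(event.critical_pressure - expected) < 3 * 0.02 * expected


class TestFitSeries:
    def test_insufficient_distinct_radii(self):
        events = [
            cav.CavitationEvent(1000.0 + i, 1.0, r)
            for i, r in enumerate([1e-3, 1e-3, 2e-3])
        ]
        with pytest.raises(InsufficientDataError, match="distinct"):
            cav.fit_cavitation_series(events)

    def test_zero_surface_tension_flat_in_radius(self):
        events = [
            cav.CavitationEvent(1050.0, 1.0, r) for r in [0.1e-3, 0.2e-3, 0.4e-3]
        ]
        fit = cav.fit_cavitation_series(events)
        assert fit.E_eff == pytest.approx(1000.0, rel=1e-10)
        assert fit.surface_tension == pytest.approx(0.0, abs=1e-12)

    def test_negative_intercept_flagged_not_clamped(self):
        # Pc stays positive at every radius but the extrapolated intercept is -50 Pa
        events = [
            cav.CavitationEvent(2.1 * 0.02 / r - 50.0, 1.0, r)
            for r in [0.1e-3, 0.2e-3, 0.4e-3]
        ]
        fit = cav.fit_cavitation_series(events)
        assert fit.E_eff < 0
        assert any("intercept" in w for w in fit.warnings)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        E=st.floats(min_value=100.0, max_value=5e4),
        gamma=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_fit_predict_identity(self, E, gamma):
        radii = [0.13e-3, 0.2065e-3, 0.419e-3, 0.597e-3]
        events = [
            cav.CavitationEvent(cav.predict_critical_pressure(E, gamma, r), 1.0, r)
            for r in radii
        ]
        fit = cav.fit_cavitation_series(events)
        assert fit.E_eff == pytest.approx(E, rel=1e-10)
        assert fit.surface_tension == pytest.approx(gamma, rel=1e-8, abs=1e-10)


class TestStrainRate:
    def test_protocol_rate_reproduced(self, clean_truth):
        trace = syn.gen_cavitation_trace(clean_truth, 0.5e-3, seed=0)
        rate = cav.cavitation_strain_rate(trace)
        assert float(rate) == pytest.approx(0.028)
        assert rate.convention == "protocol-constant"

    def test_linear_in_injection_rate(self, clean_truth):
        t1 = syn.gen_cavitation_trace(clean_truth, 0.5e-3, seed=0)
        t2 = dataclasses.replace(t1, injection_rate=2 * t1.injection_rate)
        assert float(cav.cavitation_strain_rate(t2)) == pytest.approx(
            2 * float(cav.cavitation_strain_rate(t1))
        )
        v1 = cav.cavitation_strain_rate(t1, "volumetric")
        v2 = cav.cavitation_strain_rate(t2, "volumetric")
        assert float(v2) == pytest.approx(2 * float(v1))

    def test_zero_injection_rate_rejected(self, clean_truth):
        trace = syn.gen_cavitation_trace(clean_truth, 0.5e-3, seed=0)
        bad = dataclasses.replace(trace, injection_rate=1e-30)
        object.__setattr__(bad, "injection_rate", 0.0)  # bypass trace validation
        with pytest.raises(DomainError):
            cav.cavitation_strain_rate(bad)
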