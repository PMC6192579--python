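"""Domain-type invariants, CSV round trips and unit conversion."""

import math

import numpy as np
import pandas as pd
import pytest

from tissuemech import io as tmio
from tissuemech.datamodel import (
    AnalysisConfig,
    Condition,
    ForceCurve,
    FormatError,
    ModulusRecord,
    OscillatorySweep,
    PressureTrace,
    StressStrainCurve,
    Technique,
    ValidationError,
)

TRACE_META = {
    "needle_radius_m": 0.597e-3,
    "injection_rate_m3_per_s": 8.333e-8,
    "sample_id": "s1",
}


def _trace_df(n=100):
    t = np.linspace(0, 10, n)
    return pd.DataFrame({"time_s": t, "pressure_pa": 1000 * t})


class TestValidation:
    def test_non_monotone_time_names_first_offending_index(self):
        t = np.arange(12.0)
        t[[5, 6]] = t[[6, 5]]
        with pytest.raises(ValidationError, match="index 6"):
            PressureTrace(t, np.ones(12), 1e-3, 1e-8, "s")

    def test_minimum_trace_length(self):
        with pytest.raises(ValidationError, match=">= 10"):
            PressureTrace(np.arange(5.0), np.ones(5), 1e-3, 1e-8, "s")

    @pytest.mark.parametrize("radius,rate", [(0.0, 1e-8), (1e-3, 0.0), (-1e-3, 1e-8)])
    def test_positive_geometry_required(self, radius, rate):
        with pytest.raises(ValidationError):
            PressureTrace(np.arange(10.0), np.ones(10), radius, rate, "s")

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="lengths differ"):
            OscillatorySweep(np.array([0.1, 0.2, 0.3]), np.ones(3), np.ones(2))

    def test_strain_must_start_at_zero(self):
        with pytest.raises(ValidationError, match="start at 0"):
            StressStrainCurve(np.linspace(0.1, 0.4, 20), np.ones(20), 0.027, 2e-5, 0.01)

    def test_decreasing_displacement_rejected(self):
        d = np.linspace(0, 1e-3, 30)
        d[10] = d[12]
        with pytest.raises(ValidationError):
            ForceCurve(d, np.ones(30), 5e-4, 2e-3)

    def test_modulus_record_enums_closed(self):
        with pytest.raises(ValueError):
            ModulusRecord(technique="afm", sample_id="s", young_modulus=1e3, strain_rate=0.1)
        rec = ModulusRecord(
            technique="cavitation", sample_id="s", young_modulus=1e3, strain_rate=0.1
        )
        assert rec.technique is Technique.CAVITATION
        assert rec.condition is Condition.FRESH

    def test_config_warns_at_incompressible_limit(self):
        with pytest.warns(UserWarning, match="vanishes"):
            AnalysisConfig(poisson_ratio=0.5)
        with pytest.raises(ValidationError):
            AnalysisConfig(poisson_ratio=0.6)


class TestTraceReader:
    def test_identity_read(self, tmp_path):
        path = tmp_path / "t.csv"
        _trace_df(100).to_csv(path, index=False)
        trace = tmio.read_trace_csv(path, TRACE_META)
        assert len(trace) == 100
        assert trace.needle_radius == pytest.approx(0.597e-3)
        assert trace.pressure[-1] == pytest.approx(10_000.0)

    def test_kpa_column_scaled_to_si(self, tmp_path):
        df = _trace_df(50).rename(columns={"pressure_pa": "pressure_kpa"})
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        trace = tmio.read_trace_csv(path, TRACE_META)
        assert trace.pressure[-1] == pytest.approx(10_000.0 * 1000)

    def test_psi_column_scaled_to_si(self, tmp_path):
        df = pd.DataFrame({"time_s": np.arange(10.0), "pressure_psi": np.ones(10)})
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        trace = tmio.read_trace_csv(path, TRACE_META)
        assert trace.pressure[0] == pytest.approx(6894.757293168)

    def test_shuffled_time_is_validation_error(self, tmp_path):
        df = _trace_df(50).sample(frac=1.0, random_state=0)
        path = tmp_path / "t.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="strictly increasing"):
            tmio.read_trace_csv(path, TRACE_META)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "t.csv"
        pd.DataFrame({"time_s": np.arange(10.0)}).to_csv(path, index=False)
        with pytest.raises(FormatError, match="pressure"):
            tmio.read_trace_csv(path, TRACE_META)

    def test_missing_metadata_is_error_not_default(self, tmp_path):
        path = tmp_path / "t.csv"
        _trace_df().to_csv(path, index=False)
        with pytest.raises(FormatError, match="needle_radius_m"):
            tmio.read_trace_csv(path, {"sample_id": "s", "injection_rate_m3_per_s": 1e-8})

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("time_s,pressure_pa\n")
        with pytest.raises(FormatError, match="no data rows"):
            tmio.read_trace_csv(path, TRACE_META)


class TestUniaxialReader:
    META = {
        "gauge_length_m": 0.027,
        "cross_section_area_m2": 2e-5,
        "strain_rate_per_s": 0.01,
        "sample_id": "u1",
    }

    def test_raw_columns_converted_to_engineering(self, tmp_path):
        # force 1 N over area 2e-5 m^2 -> 50 kPa; displacement = gauge -> strain 1
        df = pd.DataFrame(
            {"displacement_m": [0.0, 0.0135, 0.027], "force_n": [0.0, 0.5, 1.0]}
        )
        path = tmp_path / "u.csv"
        df.to_csv(path, index=False)
        curve = tmio.read_uniaxial_csv(path, self.META)
        assert curve.stress[-1] == pytest.approx(50_000.0)
        assert curve.strain[-1] == pytest.approx(1.0)

    def test_engineering_columns_passthrough(self, tmp_path):
        df = pd.DataFrame({"strain": [0.0, 0.1, 0.2], "stress_pa": [0.0, 340.0, 680.0]})
        path = tmp_path / "u.csv"
        df.to_csv(path, index=False)
        curve = tmio.read_uniaxial_csv(path, self.META)
        assert curve.stress[1] == pytest.approx(340.0)


class TestRoundTrips:
    """Write-then-read reproduces every numeric field to full precision."""

    def test_trace_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        trace = PressureTrace(
            np.sort(rng.uniform(0, 10, 50)), rng.uniform(0, 6000, 50),
            0.597e-3, 8.333e-8, "s1", "r1",
        )
        path = tmp_path / "t.csv"
        tmio.write_trace_csv(path, trace)
        back = tmio.read_trace_csv(
            path,
            {"needle_radius_m": 0.597e-3, "injection_rate_m3_per_s": 8.333e-8,
             "sample_id": "s1", "region_id": "r1"},
        )
        np.testing.assert_allclose(back.pressure, trace.pressure, rtol=1e-9)
        np.testing.assert_allclose(back.time, trace.time, rtol=1e-9)

    def test_sweep_round_trip(self, tmp_path):
        sweep = OscillatorySweep(
            np.linspace(0.1, 1.0, 10), np.linspace(1000, 1300, 10),
            np.linspace(200, 260, 10),
        )
        path = tmp_path / "s.csv"
        tmio.write_sweep_csv(path, sweep)
        back = tmio.read_sweep_csv(path)
        np.testing.assert_allclose(back.storage_modulus_gprime,
                                   sweep.storage_modulus_gprime, rtol=1e-9)

    def test_force_round_trip_preserves_small_forces(self, tmp_path):
        curve = ForceCurve(
            np.linspace(0, 1e-3, 40), np.linspace(0, 2e-3, 40), 5e-4, 2e-3, 10.0
        )
        path = tmp_path / "f.csv"
        tmio.write_force_csv(path, curve)
        back = tmio.read_force_csv(
            path,
            {"indenter_radius_m": 5e-4, "sample_thickness_m": 2e-3,
             "cantilever_stiffness_n_per_m": 10.0, "sample_id": "f1"},
        )
        np.testing.assert_allclose(back.force, curve.force, rtol=1e-10)

    def test_records_jsonl_round_trip(self, tmp_path):
        recs = [
            ModulusRecord(Technique.SAOS, "s1", 3300.0, 0.1,
                          rate_adjusted_modulus=3300.0),
            ModulusRecord(Technique.CAVITATION, "s2", 6100.0, 0.028,
                          condition=Condition.FROZEN_LN2),
        ]
        path = tmp_path / "r.jsonl"
        tmio.write_records_jsonl(path, recs)
        back = tmio.read_records_jsonl(path)
        assert back == recs

    def test_rigid_cantilever_survives_yaml(self, tmp_path):
        path = tmp_path / "m.yaml"
        tmio.write_metadata_yaml(path, {"cantilever_stiffness_n_per_m": math.inf})
        meta = tmio.read_metadata_yaml(path)
        assert math.isinf(meta["cantilever_stiffness_n_per_m"])
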