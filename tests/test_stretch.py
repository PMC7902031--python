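"""Stretch monitoring: gas bookkeeping, bulge-test modulus, trace analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungstretch import (
    ChamberConfig,
    InsufficientCyclesError,
    InvalidArgumentError,
    MembraneGeometry,
    PressureTrace,
    PressureTraceSpec,
    SingularStateError,
    analyze_trace,
    modulus_from_state,
    simulate_pressure_trace,
    transmembrane_pressure_from_modulus,
    volume_from_reservoir_pressure,
)


class TestVolumeFromReservoirPressure:
    def test_no_overpressure_gives_zero(self, chamber):
        assert volume_from_reservoir_pressure(98.0, chamber) == 0.0

    def test_linearized_value(self, chamber):
        # 1.5 kPa overpressure on a 30 mL headspace at 98 kPa ambient
        assert volume_from_reservoir_pressure(99.5, chamber) == pytest.approx(1.5 * 30 / 98)

    def test_isothermal_value(self, chamber):
        expected = 30 * (1 - 98 / 99.5)
        assert volume_from_reservoir_pressure(99.5, chamber, "isothermal") == pytest.approx(
            expected
        )

    def test_below_ambient_clamps_with_warning(self, chamber):
        with pytest.warns(UserWarning):
            assert volume_from_reservoir_pressure(97.0, chamber) == 0.0

    def test_nonpositive_pressure_rejected(self, chamber):
        with pytest.raises(InvalidArgumentError):
            volume_from_reservoir_pressure(0.0, chamber)

    @given(st.floats(0.01, 3.0))
    def test_modes_agree_to_first_order(self, dp):
        chamber = ChamberConfig()
        p2 = chamber.ambient_p0_kpa + dp
        lin = volume_from_reservoir_pressure(p2, chamber, "linearized")
        iso = volume_from_reservoir_pressure(p2, chamber, "isothermal")
        assert abs(lin - iso) / lin <= dp / chamber.ambient_p0_kpa + 1e-12


class TestBulgeTestModulus:
    def test_zero_deflection_gives_zero_pressure(self, geometry):
        assert transmembrane_pressure_from_modulus(0.0, 0.78, geometry) == 0.0

    def test_reference_state_value(self, geometry):
        # direct evaluation at 10% strain, E = 0.78 MPa: about 1.2 Pa
        dp = transmembrane_pressure_from_modulus(0.126, 0.78, geometry)
        assert dp == pytest.approx(1.2017e-3, rel=1e-4)

    def test_linear_in_modulus(self, geometry):
        one = transmembrane_pressure_from_modulus(0.2, 1.0, geometry)
        two = transmembrane_pressure_from_modulus(0.2, 2.0, geometry)
        assert two == pytest.approx(2 * one, rel=1e-12)

    @given(st.floats(0.01, 1.25), st.floats(0.001, 1.2))
    def test_strictly_increasing_in_deflection(self, h, dh):
        g = MembraneGeometry()
        lo = transmembrane_pressure_from_modulus(h, 0.78, g)
        hi = transmembrane_pressure_from_modulus(min(h + dh, 1.26), 0.78, g)
        if h + dh <= 1.26:
            assert hi > lo

    def test_nonpositive_modulus_rejected(self, geometry):
        with pytest.raises(InvalidArgumentError):
            transmembrane_pressure_from_modulus(0.1, 0.0, geometry)

    def test_inversion_recovers_reference_modulus(self, geometry):
        assert modulus_from_state(1.2017226998e-3, 0.126, geometry) == pytest.approx(
            0.78, rel=1e-9
        )

    @given(st.floats(0.01, 10.0), st.floats(0.005, 1.2))
    def test_forward_inverse_round_trip(self, e_mpa, h):
        g = MembraneGeometry()
        dp = transmembrane_pressure_from_modulus(h, e_mpa, g)
        assert modulus_from_state(dp, h, g) == pytest.approx(e_mpa, rel=1e-10)

    def test_zero_deflection_is_singular(self, geometry):
        with pytest.raises(SingularStateError):
            modulus_from_state(1.0, 0.0, geometry)


class TestPressureTrace:
    def test_requires_two_samples(self):
        with pytest.raises(InvalidArgumentError):
            PressureTrace(np.array([0.0]), np.array([98.0]), np.array([98.0]))

    def test_requires_monotone_time(self):
        t = np.array([0.0, 1.0, 1.0])
        p = np.full(3, 98.0)
        with pytest.raises(InvalidArgumentError):
            PressureTrace(t, p, p)

    def test_csv_round_trip(self, tmp_path):
        tr = simulate_pressure_trace(PressureTraceSpec(duration_s=5.0), seed=0)
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        back = PressureTrace.from_csv(path)
        assert back.time_s == pytest.approx(tr.time_s)
        assert back.p2_kpa == pytest.approx(tr.p2_kpa)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,p1_kpa\n0,98\n1,98\n")
        with pytest.raises(InvalidArgumentError, match="p2_kpa"):
            PressureTrace.from_csv(path)


class TestAnalyzeTrace:
    def test_noiseless_recovery_of_all_three_parameters(self, geometry, chamber):
        spec = PressureTraceSpec()  # 0.33 Hz, 10% strain, E = 0.78 MPa, 60 s
        report = analyze_trace(simulate_pressure_trace(spec, seed=0), geometry, chamber)
        resolution = 1.0 / spec.duration_s
        assert abs(report.frequency_hz - 0.33) <= resolution
        assert report.strain_mean == pytest.approx(0.10, rel=0.01)
        assert report.modulus_mean_mpa == pytest.approx(0.78, rel=0.01)

    def test_constant_trace_raises_with_partial_output(self, geometry, chamber):
        t = np.linspace(0, 10, 101)
        p = np.full(101, 98.0)
        with pytest.raises(InsufficientCyclesError) as exc:
            analyze_trace(PressureTrace(t, p, p), geometry, chamber)
        samples = exc.value.samples
        assert samples is not None
        assert samples["linear_strain"].to_numpy() == pytest.approx(np.zeros(101))

    def test_overstretch_cycles_flagged(self, geometry, chamber):
        spec = PressureTraceSpec(target_linear_strain=0.20, duration_s=30.0)
        report = analyze_trace(simulate_pressure_trace(spec, seed=0), geometry, chamber)
        assert report.per_cycle["over_stretch"].all()
        assert not report.per_cycle["beyond_membrane_limit"].any()

    def test_beyond_membrane_limit_flagged(self, geometry, chamber):
        spec = PressureTraceSpec(target_linear_strain=0.30, duration_s=30.0)
        report = analyze_trace(simulate_pressure_trace(spec, seed=0), geometry, chamber)
        assert report.per_cycle["beyond_membrane_limit"].all()

    def test_plateau_estimator_agrees_noiselessly(self, geometry, chamber):
        trace = simulate_pressure_trace(PressureTraceSpec(duration_s=30.0), seed=0)
        peak = analyze_trace(trace, geometry, chamber, modulus_estimator="peak")
        plateau = analyze_trace(trace, geometry, chamber, modulus_estimator="plateau")
        assert plateau.modulus_mean_mpa == pytest.approx(peak.modulus_mean_mpa, rel=1e-6)

    def test_frequency_recovery_across_rates(self, geometry, chamber):
        for f in (0.2, 0.33, 0.5):
            spec = PressureTraceSpec(frequency_hz=f, duration_s=40.0)
            report = analyze_trace(simulate_pressure_trace(spec, seed=1), geometry, chamber)
            assert abs(report.frequency_hz - f) <= 1.0 / spec.duration_s
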