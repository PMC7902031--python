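"""Synthetic generators: determinism, closed loops with their analysis stages."""

import numpy as np
import pytest

from lungstretch import (
    AliasingError,
    ChamberConfig,
    FluorescenceSpec,
    GravimetricSpec,
    IntensitySpec,
    MembraneGeometry,
    PressureTraceSpec,
    analyze_trace,
    empirical_porosity,
    fit_standard_curve,
    simulate_fluorescence_experiment,
    simulate_gravimetric,
    simulate_intensity_stacks,
    simulate_pressure_trace,
    substream_rng,
    translocated_fraction,
    uptake_fold_change,
    uptake_intensity,
)


class TestPressureTraceGenerator:
    def test_seed_determinism(self):
        spec = PressureTraceSpec(pressure_noise_sd_kpa=0.02, duration_s=10.0)
        a = simulate_pressure_trace(spec, seed=7)
        b = simulate_pressure_trace(spec, seed=7)
        assert np.array_equal(a.p1_kpa, b.p1_kpa)
        assert np.array_equal(a.p2_kpa, b.p2_kpa)
        c = simulate_pressure_trace(spec, seed=8)
        assert not np.array_equal(a.p2_kpa, c.p2_kpa)

    def test_zero_strain_gives_flat_ambient_trace(self, chamber):
        spec = PressureTraceSpec(target_linear_strain=0.0, duration_s=5.0)
        tr = simulate_pressure_trace(spec, seed=0)
        assert tr.p1_kpa == pytest.approx(np.full(len(tr), chamber.ambient_p0_kpa))
        assert tr.p2_kpa == pytest.approx(np.full(len(tr), chamber.ambient_p0_kpa))

    def test_undersampling_rejected(self):
        with pytest.raises(AliasingError):
            simulate_pressure_trace(PressureTraceSpec(sample_rate_hz=2.0, frequency_hz=0.33))

    def test_noiseless_closed_loop(self, geometry, chamber):
        report = analyze_trace(
            simulate_pressure_trace(PressureTraceSpec(), seed=0), geometry, chamber
        )
        assert report.strain_mean == pytest.approx(0.10, rel=0.01)
        assert report.frequency_hz == pytest.approx(0.33, abs=1 / 60)
        assert report.modulus_mean_mpa == pytest.approx(0.78, rel=0.01)

    def test_sinusoid_waveform_closed_loop(self, geometry, chamber):
        spec = PressureTraceSpec(waveform="sinusoid", duration_s=30.0)
        report = analyze_trace(simulate_pressure_trace(spec, seed=0), geometry, chamber)
        assert report.strain_mean == pytest.approx(0.10, rel=0.01)


class TestFluorescenceGenerator:
    def test_noiseless_round_trip_recovers_fraction(self):
        spec = FluorescenceSpec(relative_noise=0.0, blank_sd_au=0.0)
        curve_df, blanks, basal = simulate_fluorescence_experiment(spec, seed=0)
        curve = fit_standard_curve(curve_df["conc_ug_ml"], curve_df["fluor_au"], blanks)
        r = translocated_fraction(basal[0], curve, spec.basal_volume_ml, spec.delivered_mass_ug)
        assert r.fraction_percent == pytest.approx(30.0, rel=1e-9)

    def test_zero_true_fraction_reports_below_lod(self):
        spec = FluorescenceSpec(true_fraction_percent=0.0, relative_noise=0.0, blank_sd_au=0.5)
        curve_df, blanks, basal = simulate_fluorescence_experiment(spec, seed=0)
        curve = fit_standard_curve(curve_df["conc_ug_ml"], curve_df["fluor_au"], blanks)
        r = translocated_fraction(basal[0], curve, spec.basal_volume_ml, spec.delivered_mass_ug)
        assert r.below_lod

    def test_seed_determinism(self):
        spec = FluorescenceSpec()
        a = simulate_fluorescence_experiment(spec, seed=3)
        b = simulate_fluorescence_experiment(spec, seed=3)
        assert np.array_equal(a[1], b[1])
        assert np.array_equal(a[2], b[2])


class TestGravimetricGenerator:
    def test_noiseless_round_trip(self):
        for phi in (0.0, 0.153, 0.4):
            g = simulate_gravimetric(GravimetricSpec(true_porosity=phi), seed=0)[0]
            assert empirical_porosity(g) == pytest.approx(phi, abs=1e-12)

    def test_zero_porosity_means_equal_masses(self):
        g = simulate_gravimetric(GravimetricSpec(true_porosity=0.0), seed=0)[0]
        assert g.mass_soaked_mg == g.mass_dry_mg

    def test_blank_round_trip(self):
        spec = GravimetricSpec(true_porosity=0.153, blank_apparent_porosity=0.093)
        g = simulate_gravimetric(spec, seed=0)[0]
        assert empirical_porosity(g) == pytest.approx(0.153, abs=1e-12)

    def test_noisy_recovery_unbiased(self):
        spec = GravimetricSpec(true_porosity=0.153, weighing_noise_sd_mg=0.05, n_samples=50)
        vals = [empirical_porosity(g) for g in simulate_gravimetric(spec, seed=1)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.153) < 3 * se + 1e-12


class TestIntensityGenerator:
    def test_noiseless_fold_recovery(self):
        a, b = simulate_intensity_stacks(IntensitySpec(), seed=0)
        mean_a = np.mean([uptake_intensity(s)[0] for s in a])
        mean_b = np.mean([uptake_intensity(s)[0] for s in b])
        assert uptake_fold_change(mean_a, mean_b) == pytest.approx(2.4)

    def test_equal_means_give_unit_fold(self):
        spec = IntensitySpec(mean_condition_a_au=100.0, mean_condition_b_au=100.0)
        a, b = simulate_intensity_stacks(spec, seed=0)
        mean_a = np.mean([uptake_intensity(s)[0] for s in a])
        mean_b = np.mean([uptake_intensity(s)[0] for s in b])
        assert uptake_fold_change(mean_a, mean_b) == 1.0

    def test_seed_determinism(self):
        spec = IntensitySpec(field_noise_sd_au=5.0)
        a1, _ = simulate_intensity_stacks(spec, seed=2)
        a2, _ = simulate_intensity_stacks(spec, seed=2)
        assert a1[0].field_intensities_au == a2[0].field_intensities_au


class TestSubstreams:
    def test_named_substreams_are_independent_and_stable(self):
        a = substream_rng(1, "alpha").standard_normal(4)
        a2 = substream_rng(1, "alpha").standard_normal(4)
        b = substream_rng(1, "beta").standard_normal(4)
        assert np.array_equal(a, a2)
        assert not np.array_equal(a, b)
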