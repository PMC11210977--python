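"""In/out spectroscopy: harmonic series, smoothing, drift model, GLM, dilution."""

import numpy as np
import pytest

from mpspec.particle import ParticleModel, harmonic_spectrum, magnetization_response
from mpspec.simulate import (
    AcquisitionConfig,
    DriftModel,
    InstrumentModel,
    make_drive_waveform,
    synthesize_in_out_run,
)
from mpspec.spectroscopy import (
    GLMResult,
    HarmonicTimeSeries,
    analyze_run,
    dilution_sensitivity,
    extract_harmonic_series,
    fit_drift_model,
    fit_glm,
    remove_drift,
    rolling_average,
    simple_in_out_amplitude,
)


def make_series(values, states):
    return HarmonicTimeSeries(values, states, np.arange(len(states)))


class TestExtractHarmonicSeries:
    def test_noiseless_amplitudes_constant_across_measurements(
        self, short_config, ideal_instrument, debye_particle
    ):
        mset = synthesize_in_out_run(debye_particle, short_config, ideal_instrument)
        series = extract_harmonic_series(mset, n_harmonics=7)
        in_vals = series.values[series.in_mask]
        spread = np.abs(in_vals - in_vals[0]).max()
        assert spread <= 1e-10 * np.abs(in_vals[0]).max()

    def test_out_measurements_zero_without_feedthrough(
        self, short_config, ideal_instrument, debye_particle
    ):
        mset = synthesize_in_out_run(debye_particle, short_config, ideal_instrument)
        series = extract_harmonic_series(mset, n_harmonics=7)
        out_vals = series.values[series.out_mask]
        assert np.abs(out_vals).max() <= 1e-12 * np.abs(series.values).max()

    def test_matches_underlying_moment_spectrum(
        self, short_config, ideal_instrument, debye_particle
    ):
        mset = synthesize_in_out_run(debye_particle, short_config, ideal_instrument)
        series = extract_harmonic_series(mset, n_harmonics=7)
        fw = make_drive_waveform(short_config)
        m = magnetization_response(fw, debye_particle)
        direct = harmonic_spectrum(m, short_config.samples_per_drive_period, 7)
        recovered = series.values[series.in_mask][0]
        assert np.abs(recovered - direct).max() <= 1e-6 * np.abs(direct).max()


class TestRollingAverage:
    def test_constant_series_unchanged(self):
        series = make_series(np.ones((22, 2), complex), ["out"] * 11 + ["in"] * 11)
        np.testing.assert_allclose(rolling_average(series).values, 1.0)

    def test_linear_series_interior_unchanged(self):
        vals = np.arange(11.0)[:, None] + 0j
        series = make_series(vals, ["out"] * 11)
        smoothed = rolling_average(series)
        np.testing.assert_allclose(smoothed.values[2:-2], vals[2:-2], atol=1e-12)

    def test_does_not_cross_state_boundaries(self):
        # a step between states must survive smoothing exactly
        vals = np.r_[np.zeros(11), np.ones(11)][:, None] + 0j
        series = make_series(vals, ["out"] * 11 + ["in"] * 11)
        smoothed = rolling_average(series)
        np.testing.assert_allclose(smoothed.values, vals, atol=1e-12)

    def test_white_noise_variance_reduced_fivefold(self):
        rng = np.random.default_rng(0)
        center = []
        for _ in range(1000):
            vals = rng.normal(size=(11, 1)) + 0j
            smoothed = rolling_average(make_series(vals, ["out"] * 11))
            center.append(smoothed.values[5, 0].real)
        # variance of the centred 5-point mean across replicates is sigma^2/5
        assert 1.0 / np.var(center) == pytest.approx(5.0, rel=0.10)

    def test_short_segment_warns(self):
        series = make_series(np.zeros((3, 1), complex), ["out"] * 3)
        with pytest.warns(RuntimeWarning, match="unsmoothed"):
            rolling_average(series)


class TestDriftModel:
    def test_drift_free_run_near_zero_slope(self, short_config, tf):
        inst = InstrumentModel(tf=tf, drift=DriftModel.none())
        p = ParticleModel(0.0, 1.0)
        mset = synthesize_in_out_run(p, short_config, inst, seed=2)
        series = extract_harmonic_series(mset, n_harmonics=3)
        drift = fit_drift_model(series)
        noise_scale = np.abs(series.values[series.out_mask]).std()
        assert np.abs(drift.slope).max() * 55 < 6 * noise_scale

    def test_injected_drift_recovered(self, short_config, tf):
        # 0.1%/100-measurement magnitude drift on the feedthrough fundamental
        rates = []
        for seed in range(100):
            inst = InstrumentModel(
                tf=tf, drift=DriftModel(1e-5, 0.0), noise_density=1e-10
            )
            mset = synthesize_in_out_run(ParticleModel(0.0, 1.0), short_config, inst, seed=seed)
            series = extract_harmonic_series(mset, n_harmonics=1)
            drift = fit_drift_model(series)
            feed = np.abs(series.values[0, 0])
            rates.append(np.abs(drift.slope[0]) / feed)
        assert np.mean(rates) == pytest.approx(1e-5, rel=0.15)

    def test_drift_removal_leaves_noise_level_residual(self, short_config, tf):
        for seed in range(20):
            inst = InstrumentModel(tf=tf, drift=DriftModel(1e-4, 1e-4), noise_density=3.3e-9)
            mset = synthesize_in_out_run(ParticleModel(0.0, 1.0), short_config, inst, seed=seed)
            series = extract_harmonic_series(mset, n_harmonics=1)
            corrected = remove_drift(series)
            inst0 = InstrumentModel(tf=tf, drift=DriftModel.none(), noise_density=3.3e-9)
            mset0 = synthesize_in_out_run(ParticleModel(0.0, 1.0), short_config, inst0, seed=seed)
            pure_noise = extract_harmonic_series(mset0, n_harmonics=1)
            resid_sd = corrected.values[corrected.out_mask, 0].std()
            noise_sd = pure_noise.values[pure_noise.out_mask, 0].std()
            assert resid_sd <= 1.25 * noise_sd

    def test_too_few_out_measurements(self):
        series = make_series(np.zeros((6, 1), complex), ["out"] * 3 + ["in"] * 3)
        with pytest.raises(ValueError):
            fit_drift_model(series)


class TestGLM:
    def test_exact_recovery_on_noiseless_run(
        self, short_config, ideal_instrument, debye_particle
    ):
        mset = synthesize_in_out_run(debye_particle, short_config, ideal_instrument)
        series = extract_harmonic_series(mset, n_harmonics=5)
        glm = fit_glm(series)
        fw = make_drive_waveform(short_config)
        m = magnetization_response(fw, debye_particle)
        truth = harmonic_spectrum(m, short_config.samples_per_drive_period, 5)
        assert np.abs(glm.signal_amplitude - truth).max() <= 1e-10 * np.abs(truth).max()

    def test_matches_normal_equations_oracle(self, short_config, noisy_instrument):
        p = ParticleModel(1e-8, 1.0)
        mset = synthesize_in_out_run(p, short_config, noisy_instrument, seed=4)
        series = extract_harmonic_series(mset, n_harmonics=6)
        glm = fit_glm(series)
        x = series.indices
        design = np.column_stack([np.ones_like(x), x, series.in_mask.astype(float)])
        oracle = np.linalg.inv(design.T @ design) @ design.T @ series.values
        assert np.abs(glm.signal_amplitude - oracle[2]).max() <= 1e-10 * np.abs(
            oracle[2]
        ).max()
        assert np.abs(glm.constant - oracle[0]).max() <= 1e-10 * np.abs(oracle).max()

    def test_invariant_to_constant_and_linear_trend(self, short_config, noisy_instrument):
        p = ParticleModel(1e-8, 1.0)
        mset = synthesize_in_out_run(p, short_config, noisy_instrument, seed=6)
        series = extract_harmonic_series(mset, n_harmonics=3)
        glm = fit_glm(series)
        shifted = series.replace_values(
            series.values + (2.5 - 1j) + (0.3 + 0.7j) * series.indices[:, None]
        )
        glm2 = fit_glm(shifted)
        assert np.abs(glm2.signal_amplitude - glm.signal_amplitude).max() <= 1e-10 * (
            np.abs(glm.signal_amplitude).max() + 1
        )

    def test_snr_invariant_definition(self, short_config, noisy_instrument):
        p = ParticleModel(1e-7, 1.0)
        mset = synthesize_in_out_run(p, short_config, noisy_instrument, seed=7)
        _, glm = analyze_run(mset, n_harmonics=5)
        np.testing.assert_allclose(
            glm.snr, np.abs(glm.signal_amplitude) / glm.residual_sd
        )
        assert np.all(glm.residual_sd >= 0)

    def test_rank_deficient_schedule_rejected(self):
        series = make_series(np.zeros((10, 1), complex), ["out"] * 10)
        with pytest.raises(ValueError, match="rank"):
            fit_glm(series)

    def test_rejects_strong_drift_without_inflating_noise(self, short_config, tf):
        # drift 10x the white-noise sd must not inflate residual_sd by >20%
        noise = 3.3e-9
        inflations = []
        for seed in range(100):
            inst = InstrumentModel(tf=tf, drift=DriftModel(0.0, 0.0), noise_density=noise)
            mset = synthesize_in_out_run(ParticleModel(0.0, 1.0), short_config, inst, seed=seed)
            base = analyze_run(mset, n_harmonics=1)[1].residual_sd[0]
            # amplitude drift sized to 10x that baseline noise over the run
            feed_amp = 7.5e-5
            rate = 10 * base / (feed_amp * 55)
            inst_d = InstrumentModel(tf=tf, drift=DriftModel(rate, 0.0), noise_density=noise)
            mset_d = synthesize_in_out_run(ParticleModel(0.0, 1.0), short_config, inst_d, seed=seed)
            drifted = analyze_run(mset_d, n_harmonics=1)[1].residual_sd[0]
            inflations.append(drifted / base)
        assert np.mean(inflations) < 1.2

    def test_full_pipeline_linear_over_three_decades(self, short_config, ideal_instrument):
        masses = np.geomspace(1e-9, 1e-6, 7)
        amps = []
        for msat in masses:
            p = ParticleModel(msat, 1.0)
            mset = synthesize_in_out_run(p, short_config, ideal_instrument)
            _, glm = analyze_run(mset, n_harmonics=3)
            amps.append(np.abs(glm.signal_amplitude[2]))
        amps = np.asarray(amps)
        corr = np.corrcoef(masses, amps)[0, 1]
        assert corr**2 > 0.999


class TestSimpleInOut:
    def test_matches_glm_on_noiseless_data(self, short_config, ideal_instrument, debye_particle):
        mset = synthesize_in_out_run(debye_particle, short_config, ideal_instrument)
        series = extract_harmonic_series(mset, n_harmonics=3)
        naive = simple_in_out_amplitude(series)
        glm = fit_glm(series)
        assert np.abs(naive - glm.signal_amplitude).max() <= 1e-10 * np.abs(naive).max()


class TestDilutionSensitivity:
    @staticmethod
    def synthetic_results(masses, slope, noise):
        results = []
        for m in masses:
            amp = np.array([slope * m + 0j])
            results.append(
                GLMResult(
                    signal_amplitude=amp,
                    constant=np.zeros(1, complex),
                    trend=np.zeros(1, complex),
                    residual_sd=np.array([noise * np.sqrt(2)]),
                    amplitude_se=np.array([noise]),
                    snr=np.abs(amp) / noise,
                    zscore=amp.real / noise,
                )
            )
        return results

    def test_exact_linear_series_analytic_limit(self):
        masses = np.geomspace(1e-12, 1e-8, 8)
        slope, noise = 36.7, 1e-12
        res = self.synthetic_results(masses, slope, noise)
        sens = dilution_sensitivity(masses, res, harmonic=1)
        assert sens.slope == pytest.approx(slope, rel=1e-9)
        assert sens.mass_at_snr1 == pytest.approx(noise / slope, rel=1e-9)
        assert sens.mass_at_snr5 == pytest.approx(5 * noise / slope, rel=1e-9)

    def test_signal_scaling_homogeneity(self):
        masses = np.geomspace(1e-12, 1e-8, 8)
        res1 = self.synthetic_results(masses, 10.0, 1e-12)
        res2 = self.synthetic_results(masses, 20.0, 1e-12)
        s1 = dilution_sensitivity(masses, res1, harmonic=1)
        s2 = dilution_sensitivity(masses, res2, harmonic=1)
        assert s2.mass_at_snr1 == pytest.approx(s1.mass_at_snr1 / 2.0)

    def test_simulated_series_recovers_injected_sensitivity(self, tf):
        # the fitted slope (Am^2 of third harmonic per kg Fe) must match the
        # moment-per-mass sensitivity the generator was given
        cfg = AcquisitionConfig.spectroscopy(n_drive_periods=100)
        inst = InstrumentModel(tf=tf)
        masses = np.geomspace(3e-11, 3e-8, 6)
        m_per_kg = 110.0  # Am^2 per kg Fe at saturation
        fw = make_drive_waveform(cfg)
        per_kg_particle = ParticleModel(m_per_kg, 1.0)
        m_unit = magnetization_response(fw, per_kg_particle)
        expected_slope = np.abs(
            harmonic_spectrum(m_unit, cfg.samples_per_drive_period, 3)[2]
        )
        slopes, limits = [], []
        for seed in range(10):
            results = []
            for i, mass in enumerate(masses):
                p = ParticleModel(mass * m_per_kg, 1.0)
                mset = synthesize_in_out_run(p, cfg, inst, seed=seed * 100 + i)
                results.append(analyze_run(mset, n_harmonics=3)[1])
            sens = dilution_sensitivity(masses, results, harmonic=3)
            slopes.append(sens.slope)
            limits.append(sens.mass_at_snr1)
        assert np.mean(slopes) == pytest.approx(expected_slope, rel=0.20)
        # detection limit is internally consistent with floor/slope
        assert np.all(np.isfinite(limits)) and np.all(np.asarray(limits) > 0)

    def test_too_few_points_rejected(self):
        res = self.synthetic_results(np.array([1e-9, 1e-8]), 1.0, 1e-12)
        with pytest.raises(ValueError):
            dilution_sensitivity(np.array([1e-9, 1e-8]), res, harmonic=1)
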