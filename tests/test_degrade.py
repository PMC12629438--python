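"""Degradation stages: filter, resample, noise, percentile matching, jitter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gazedegrade.degrade import (
    DEFAULT_CALIBRATION,
    CalibrationModel,
    DegradationPlan,
    NoiseModel,
    PlanConfig,
    add_precision_noise,
    antialias_filter,
    degrade,
    draw_fixation_degradations,
    eccentricity_weight,
    fit_noise_regression,
    inject_accuracy_offsets,
    jitter_timestamps,
    percentile_rank,
    plan_baseline_degradation,
    plan_percentile_degradation,
    quantile_lookup,
    required_noise_variance,
    resample_spline,
)
from gazedegrade.io import GazeRecording, percentile_profile_from_values
from gazedegrade.quality import (
    GAUSSIAN_MAD_FACTOR,
    QualityConfig,
    extract_fixation_windows,
    quality_profile,
    temporal_precision,
)
from gazedegrade.sim import SimQualitySpec, simulate_recording, simulate_stimulus

from conftest import synthetic_target_profiles


def _sine_recording(freq_hz: float, rate_hz: float = 1000.0, seconds: float = 4.0):
    t = np.arange(0.0, seconds * 1000.0, 1000.0 / rate_hz)
    x = np.sin(2 * np.pi * freq_hz * t / 1000.0)
    return GazeRecording(t, x, np.zeros_like(t), nominal_rate=rate_hz)


def _amplitude(rec: GazeRecording, freq_hz: float) -> float:
    sel = slice(rec.n_samples // 4, 3 * rec.n_samples // 4)  # skip edge transients
    t = rec.timestamps[sel] / 1000.0
    phasor = np.exp(-2j * np.pi * freq_hz * t)
    return 2.0 * np.abs(np.mean(rec.x[sel] * phasor))


class TestAntialiasFilter:
    def test_dc_passband_identity(self):
        t = np.arange(0.0, 2000.0)
        rec = GazeRecording(t, np.full(t.size, 3.5), np.full(t.size, -1.0), 1000.0)
        out = antialias_filter(rec, 250.0)
        np.testing.assert_allclose(out.x, 3.5, atol=1e-9)
        np.testing.assert_allclose(out.y, -1.0, atol=1e-9)

    def test_half_cutoff_barely_attenuated_zero_phase(self):
        cutoff = 0.8 * 250.0 / 2.0  # 100 Hz
        rec = _sine_recording(cutoff / 2.0)
        out = antialias_filter(rec, 250.0)
        assert _amplitude(out, cutoff / 2.0) > 0.99
        # zero-phase: no phase lag between filtered and original phasors
        sel = slice(1000, 3000)
        t = rec.timestamps[sel] / 1000.0
        phasor = np.exp(-2j * np.pi * (cutoff / 2.0) * t)
        lag = np.angle(np.mean(out.x[sel] * phasor) / np.mean(rec.x[sel] * phasor))
        assert abs(lag) < 1e-3

    def test_stopband_attenuation_monotone(self):
        cutoff = 100.0
        amps = []
        for mult in (2.0, 3.0, 4.0):
            out = antialias_filter(_sine_recording(cutoff * mult), 250.0)
            amps.append(_amplitude(out, cutoff * mult))
        assert amps[0] < 0.01
        assert amps[0] > amps[1] > amps[2]

    def test_upsampling_rejected(self):
        rec = _sine_recording(10.0, rate_hz=250.0)
        with pytest.raises(ValueError, match="target rate"):
            antialias_filter(rec, 1000.0)

    def test_invalid_gaps_interpolated_and_reflagged(self):
        t = np.arange(0.0, 1000.0)
        x = np.ones(t.size)
        x[500:510] = np.nan
        rec = GazeRecording(t, x, np.zeros_like(t), 1000.0)
        out = antialias_filter(rec, 250.0)
        assert np.isfinite(out.x).all()
        assert not out.validity[505]


class TestResample:
    def test_identity_at_knots(self, rng):
        t = np.arange(0.0, 100.0)
        rec = GazeRecording(t, rng.normal(size=100), rng.normal(size=100), 1000.0)
        out = resample_spline(rec, t)
        np.testing.assert_allclose(out.x, rec.x, atol=1e-12)

    def test_linear_signal_reproduced_exactly(self, rng):
        t = np.arange(0.0, 1000.0)
        rec = GazeRecording(t, 0.01 * t + 2.0, -0.02 * t, 1000.0)
        new_t = np.sort(rng.uniform(0.0, 999.0, 257))
        out = resample_spline(rec, new_t)
        np.testing.assert_allclose(out.x, 0.01 * new_t + 2.0, atol=1e-9)

    def test_downsample_grid_arithmetic(self):
        rec = _sine_recording(5.0, seconds=10.0)
        step = 4.0
        grid = np.arange(rec.timestamps[0], rec.timestamps[-1], step)
        out = resample_spline(rec, grid)
        assert abs(out.n_samples - 2500) <= 1

    def test_extrapolation_rejected(self):
        rec = _sine_recording(5.0, seconds=1.0)
        with pytest.raises(ValueError, match="outside the source support"):
            resample_spline(rec, np.array([-1.0, 0.0]))


class TestNoiseModel:
    def test_weight_is_one_at_screen_edge(self):
        model = NoiseModel(0.1, eccentricity_enabled=True, sigma_s=20.0, r_max=20.0)
        assert eccentricity_weight(20.0, 0.0, model) == pytest.approx(1.0)

    def test_weight_at_center(self):
        model = NoiseModel(0.1, eccentricity_enabled=True, sigma_s=20.0, r_max=20.0)
        assert eccentricity_weight(0.0, 0.0, model) == pytest.approx(np.exp(-0.5))

    def test_disabled_weight_is_identity(self):
        model = NoiseModel(0.1)
        np.testing.assert_array_equal(
            eccentricity_weight(np.array([0.0, 5.0, 20.0]), np.zeros(3), model), 1.0
        )

    def test_zero_variance_is_identity(self, rng):
        rec = _sine_recording(5.0)
        out = add_precision_noise(rec, NoiseModel(0.0), rng)
        np.testing.assert_array_equal(out.x, rec.x)

    def test_noise_mad_matches_gaussian_closed_form(self, rng):
        sigma0_sq = 0.09
        stim = simulate_stimulus(30, (1200.0, 1500.0), 15.0, np.random.default_rng(3))
        rec = simulate_recording(stim, SimQualitySpec(fixation_noise_sd=0.0), rng)
        noisy = add_precision_noise(rec, NoiseModel(sigma0_sq), rng)
        prof = quality_profile(noisy, stim)
        sigma = np.sqrt(sigma0_sq)
        assert prof.mad_h == pytest.approx(GAUSSIAN_MAD_FACTOR * sigma, rel=0.05)
        assert prof.mad_c == pytest.approx(np.sqrt(2) * GAUSSIAN_MAD_FACTOR * sigma, rel=0.05)

    def test_deterministic_under_seed(self):
        rec = _sine_recording(5.0)
        a = add_precision_noise(rec, NoiseModel(0.04), np.random.default_rng(9))
        b = add_precision_noise(rec, NoiseModel(0.04), np.random.default_rng(9))
        np.testing.assert_array_equal(a.x, b.x)


class TestCalibration:
    def test_packaged_defaults(self):
        assert required_noise_variance(0.0) == pytest.approx(0.0356, abs=1e-12)
        slope = required_noise_variance(1.0) - required_noise_variance(0.0)
        assert slope == pytest.approx(1.2904, abs=1e-12)

    def test_negative_delta_clamps_to_zero(self):
        assert required_noise_variance(-1.0) == 0.0

    def test_refit_positive_slope_on_noiseless_sources(self):
        rng = np.random.default_rng(21)
        pairs = []
        for _ in range(2):
            stim = simulate_stimulus(10, (1200.0, 1500.0), 15.0, rng)
            pairs.append(
                (simulate_recording(stim, SimQualitySpec(fixation_noise_sd=0.02), rng), stim)
            )
        grid = np.array([0.01, 0.05, 0.1, 0.2, 0.4])
        model = fit_noise_regression(pairs, grid, seed=0)
        assert model.slope > 0
        # on near-noiseless sources dMAD_c ~ sqrt(2)*0.6745*sigma0, so the
        # sigma0^2-vs-dMAD relation is convex with positive OLS slope
        assert model.fit_diagnostics["r_squared"] > 0.9

    def test_refit_deterministic(self):
        rng = np.random.default_rng(22)
        stim = simulate_stimulus(8, (1200.0, 1500.0), 15.0, rng)
        rec = simulate_recording(stim, SimQualitySpec(fixation_noise_sd=0.05), rng)
        grid = np.array([0.02, 0.1, 0.3])
        a = fit_noise_regression([(rec, stim)], grid, seed=5)
        b = fit_noise_regression([(rec, stim)], grid, seed=5)
        assert (a.slope, a.intercept) == (b.slope, b.intercept)


class TestPercentileMatching:
    def test_median_rank_of_odd_profile(self):
        prof = percentile_profile_from_values([1.0, 2.0, 3.0], "m")
        assert percentile_rank(2.0, prof) == pytest.approx(0.5)

    def test_clamping_outside_range(self):
        prof = percentile_profile_from_values([1.0, 2.0, 3.0], "m")
        assert percentile_rank(0.0, prof) == 0.0
        assert percentile_rank(9.0, prof) == 1.0

    def test_quantile_endpoints_and_median(self):
        prof = percentile_profile_from_values([1.0, 2.0, 3.0], "m")
        assert quantile_lookup(0.0, prof) == 1.0
        assert quantile_lookup(1.0, prof) == 3.0
        assert quantile_lookup(0.5, prof) == 2.0

    def test_uniform_profile_plotting_positions(self):
        prof = percentile_profile_from_values(np.arange(1.0, 101.0), "m")
        assert quantile_lookup(0.25, prof) == pytest.approx(25.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
            min_size=2,
            max_size=40,
            unique=True,
        )
    )
    def test_rank_quantile_round_trip(self, values):
        prof = percentile_profile_from_values(values, "m")
        for v in prof.sorted_values:
            assert quantile_lookup(percentile_rank(float(v), prof), prof) == pytest.approx(
                float(v), rel=1e-9, abs=1e-9
            )


def _quality_profiles_from_mads(mads, rid_prefix="s"):
    from gazedegrade.io import QualityProfile

    return [
        QualityProfile(
            recording_id=f"{rid_prefix}{i}",
            theta_h=0.3,
            theta_v=0.3,
            theta_c=0.4,
            mad_h=m / np.sqrt(2),
            mad_v=m / np.sqrt(2),
            mad_c=m,
            temporal_precision_ms=0.0,
        )
        for i, m in enumerate(mads)
    ]


class TestPlanning:
    def test_matched_distributions_give_zero_delta(self):
        mads = np.linspace(0.1, 0.5, 20)
        source = _quality_profiles_from_mads(mads)
        target = synthetic_target_profiles()
        target["mad_c"] = percentile_profile_from_values(mads, "mad_c")
        plans = plan_percentile_degradation(source, target, DEFAULT_CALIBRATION)
        for plan in plans:
            assert plan.sigma0_sq == pytest.approx(0.0356, abs=1e-9)

    def test_rank_preserved_at_extremes(self):
        # the source maximum maps to the target maximum, the minimum to
        # the minimum, for any equal-size target distribution
        source = percentile_profile_from_values(np.linspace(0.1, 0.5, 20), "mad_c")
        target = percentile_profile_from_values(np.linspace(0.3, 2.0, 20) ** 2, "mad_c")
        p_max = percentile_rank(0.5, source)
        p_min = percentile_rank(0.1, source)
        assert quantile_lookup(p_max, target) == pytest.approx(4.0)
        assert quantile_lookup(p_min, target) == pytest.approx(0.09)

    def test_uniformly_shifted_target_gives_constant_delta(self):
        mads = np.linspace(0.1, 0.5, 50)
        source = _quality_profiles_from_mads(mads)
        target = synthetic_target_profiles()
        target["mad_c"] = percentile_profile_from_values(mads + 0.1, "mad_c")
        plans = plan_percentile_degradation(source, target, DEFAULT_CALIBRATION)
        expected = required_noise_variance(0.1)
        for plan in plans:
            assert plan.sigma0_sq == pytest.approx(expected, abs=1e-9)

    def test_plans_never_negative(self):
        rng = np.random.default_rng(0)
        source = _quality_profiles_from_mads(rng.uniform(0.1, 2.0, 30))
        target = synthetic_target_profiles()
        for planner in (plan_percentile_degradation, plan_baseline_degradation):
            for plan in planner(source, target, DEFAULT_CALIBRATION):
                assert plan.sigma0_sq >= 0
                assert plan.delta_theta_h >= 0 and plan.delta_theta_v >= 0

    def test_missing_target_profile_is_an_error(self):
        source = _quality_profiles_from_mads(np.linspace(0.1, 0.5, 5))
        target = synthetic_target_profiles()
        del target["theta_v"]
        with pytest.raises(ValueError, match="theta_v"):
            plan_percentile_degradation(source, target, DEFAULT_CALIBRATION)


class TestAccuracyInjection:
    def test_coverage_rule_monte_carlo(self):
        rng = np.random.default_rng(0)
        draws = draw_fixation_degradations(1.0, 1_000_000, rng, rel_tol=0.2)
        fraction = np.mean((draws >= 0.8) & (draws <= 1.2))
        assert fraction == pytest.approx(0.9973, abs=0.001)

    def test_zero_delta_is_identity(self, noiseless_pair, rng):
        rec, stim = noiseless_pair
        windows = extract_fixation_windows(stim, 200.0)
        out = inject_accuracy_offsets(rec, windows, 0.0, 0.0, rng)
        np.testing.assert_array_equal(out.x, rec.x)

    def test_theta_converges_to_delta(self):
        rng = np.random.default_rng(4)
        stim = simulate_stimulus(40, (1200.0, 1500.0), 15.0, rng)
        rec = simulate_recording(stim, SimQualitySpec(fixation_noise_sd=0.0), rng)
        windows = extract_fixation_windows(stim, 200.0)
        out = inject_accuracy_offsets(rec, windows, 0.5, 0.0, rng)
        prof = quality_profile(out, stim)
        # |s*d| = d and E[d] = 0.5; with 40 fixations the mean is tight
        assert prof.theta_h == pytest.approx(0.5, rel=0.05)
        assert prof.theta_v == pytest.approx(0.0, abs=1e-9)

    def test_samples_outside_windows_untouched(self, noiseless_pair):
        rec, stim = noiseless_pair
        windows = extract_fixation_windows(stim, 200.0)
        out = inject_accuracy_offsets(rec, windows, 0.7, 0.7, np.random.default_rng(1))
        in_window = np.zeros(rec.n_samples, dtype=bool)
        for w in windows:
            in_window |= (rec.timestamps >= w.start_ms) & (rec.timestamps < w.end_ms)
        np.testing.assert_array_equal(out.x[~in_window], rec.x[~in_window])
        assert np.all(out.x[in_window] != rec.x[in_window])


class TestTimestampJitter:
    def test_zero_jitter_is_identity(self, rng):
        grid = np.arange(0.0, 100.0, 4.0)
        np.testing.assert_array_equal(jitter_timestamps(grid, 0.0, rng), grid)

    def test_measured_isi_sd_is_sqrt2_sigma(self, rng):
        grid = np.arange(0.0, 200_000.0, 4.0)
        out = jitter_timestamps(grid, 0.35, rng)
        assert temporal_precision(out) == pytest.approx(np.sqrt(2) * 0.35, rel=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_strictly_increasing_for_all_seeds(self, seed):
        grid = np.arange(0.0, 4000.0, 4.0)
        out = jitter_timestamps(grid, 0.6, np.random.default_rng(seed))
        assert np.all(np.diff(out) > 0)
        assert out[0] == grid[0]

    def test_excessive_jitter_rejected(self, rng):
        with pytest.raises(ValueError, match="too large"):
            jitter_timestamps(np.arange(0.0, 100.0, 4.0), 1.0, rng)


class TestDegrade:
    def test_modes_agree_when_all_deltas_zero(self, noiseless_pair):
        rec, stim = noiseless_pair
        plan = DegradationPlan(
            recording_id=rec.recording_id, target_rate_hz=250.0, sigma0_sq=0.0, seed=3
        )
        a = degrade(rec, stim, plan, mode="percentile")
        b = degrade(rec, stim, plan, mode="baseline")
        np.testing.assert_array_equal(a.timestamps, b.timestamps)
        np.testing.assert_array_equal(a.x, b.x)

    def test_bit_identical_under_same_seed(self, noiseless_pair):
        rec, stim = noiseless_pair
        plan = DegradationPlan(
            recording_id=rec.recording_id,
            target_rate_hz=250.0,
            sigma0_sq=0.05,
            delta_theta_h=0.2,
            delta_theta_v=0.1,
            jitter_sd_ms=0.3,
            seed=17,
        )
        a = degrade(rec, stim, plan, mode="percentile")
        b = degrade(rec, stim, plan, mode="percentile")
        np.testing.assert_array_equal(a.timestamps, b.timestamps)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_output_nominal_isi_is_4ms(self, noiseless_pair):
        rec, stim = noiseless_pair
        plan = DegradationPlan(recording_id=rec.recording_id, target_rate_hz=250.0, seed=0)
        out = degrade(rec, stim, plan, mode="baseline")
        assert out.nominal_rate == 250.0
        assert np.median(np.diff(out.timestamps)) == pytest.approx(4.0, abs=1e-9)

    def test_calibrated_jitter_reproduces_target_temporal_precision(self):
        rng = np.random.default_rng(8)
        stim = simulate_stimulus(30, (1200.0, 1500.0), 15.0, rng)
        rec = simulate_recording(stim, SimQualitySpec(fixation_noise_sd=0.05), rng)
        target_tp = 0.5
        plan = DegradationPlan(
            recording_id=rec.recording_id,
            target_rate_hz=250.0,
            jitter_sd_ms=target_tp / np.sqrt(2),
            seed=2,
        )
        out = degrade(rec, stim, plan, mode="percentile")
        assert temporal_precision(out.timestamps) == pytest.approx(target_tp, rel=0.10)
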