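"""Smoothing, event detection, growth rates and stage rescaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormgrowth import synthetic as syn
from wormgrowth import trajectory as tj


class TestMedianFilter:
    def test_spike_removed(self):
        out = tj.median_filter(np.array([1.0, 100.0, 1.0]))
        assert out[1] == 1.0

    def test_monotone_series_unchanged(self):
        x = np.cumsum(np.abs(np.arange(20)))
        assert np.array_equal(tj.median_filter(x.astype(float)), x)

    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 2.0])
        assert np.array_equal(tj.median_filter(x, 1), x)

    def test_gaps_not_bridged(self):
        x = np.array([1.0, 1.0, np.nan, 5.0, 5.0])
        out = tj.median_filter(x)
        assert np.isnan(out[2]) and out[1] == 1.0 and out[3] == 5.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            tj.median_filter(np.zeros(5), 4)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40))
    def test_output_within_input_range(self, data):
        x = np.array(data)
        out = tj.median_filter(x)
        assert np.all(out >= x.min() - 1e-12) and np.all(out <= x.max() + 1e-12)


class TestRlowess:
    def test_exact_line_reproduced(self):
        x = np.arange(40, dtype=float)
        y = 3.0 - 0.25 * x
        assert np.abs(tj.rlowess_smooth(y) - y).max() < 1e-9

    def test_single_large_outlier_suppressed(self):
        x = np.arange(60, dtype=float)
        y = 10.0 + 0.5 * x
        yy = y.copy()
        yy[30] = y[30] * 10
        sm = tj.rlowess_smooth(yy)
        assert abs(sm[30] - y[30]) / y[30] < 0.01

    def test_constant_series_constant(self):
        out = tj.rlowess_smooth(np.full(30, 4.2))
        assert np.allclose(out, 4.2)

    def test_short_series_linear_fallback(self):
        y = 1.0 + 2.0 * np.arange(8, dtype=float)
        assert np.abs(tj.rlowess_smooth(y, window=15) - y).max() < 1e-9


class TestWhittaker:
    def test_lambda_zero_identity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        assert np.array_equal(tj.whittaker_smooth(y, lam=0.0), y)

    def test_infinite_lambda_is_ols_line(self):
        z = tj.whittaker_smooth(np.array([1.0, 2.0, 4.0]), np.array([0.0, 1.0, 2.0]), 1e9, 2)
        assert np.abs(z - np.array([5 / 6, 7 / 3, 23 / 6])).max() < 1e-6

    def test_banded_equals_dense_solve(self):
        rng = np.random.default_rng(3)
        x = np.arange(80) / 6.0
        y = rng.normal(size=80)
        d = tj._divided_diff_matrix(x, 2).toarray()
        dense = np.linalg.solve(np.eye(80) + 0.75 * d.T @ d, y)
        assert np.abs(dense - tj.whittaker_smooth(y, x, 0.75, 2)).max() < 1e-10

    def test_nonuniform_grid_supported(self):
        x = np.array([0.0, 0.3, 1.0, 1.1, 2.5, 3.0])
        y = 1.0 + 2.0 * x
        # lines are in the penalty null space at any lambda
        assert np.abs(tj.whittaker_smooth(y, x, 50.0, 2) - y).max() < 1e-8

    def test_decreasing_x_rejected(self):
        with pytest.raises(ValueError):
            tj.whittaker_smooth(np.zeros(4), np.array([0.0, 1.0, 1.0, 2.0]))


class TestDetectHatch:
    def test_hatch_found_after_egg_frames(self):
        times = np.arange(60) / 6.0
        elong = np.where(np.arange(60) >= 30, 8.0, 1.5)
        accepted = np.ones(60, bool)
        t, method = tj.detect_hatch(times, elong, accepted)
        assert t == pytest.approx(times[30]) and method == "auto"

    def test_movie_starting_post_hatch_left_censored(self):
        times = np.arange(20) / 6.0
        t, method = tj.detect_hatch(times, np.full(20, 8.0), np.ones(20, bool))
        assert t == times[0] and method == "left-censored"

    def test_override_wins(self):
        t, method = tj.detect_hatch(np.arange(5.0), np.ones(5), np.ones(5, bool), override=2.5)
        assert t == 2.5 and method == "override"

    def test_never_detected_raises(self):
        with pytest.raises(ValueError):
            tj.detect_hatch(np.arange(10.0), np.ones(10), np.zeros(10, bool))


class TestDetectMolts:
    def test_constructed_two_slope_signal_single_peak(self):
        # slope 0.10/h for 12 h, 2 h plateau, then 0.12/h
        t = np.arange(0, 24, 1 / 6)
        logv = np.where(
            t < 12, 0.1 * t, np.where(t < 14, 1.2, 1.2 + 0.12 * (t - 14))
        )
        tr = tj.AnimalTrajectory(times=t, volume=np.exp(logv))
        ann = tj.detect_molts(tr, tj.AnalysisConfig(n_molts=1), hatch_time=0.0)
        assert ann.molt_times[0] == pytest.approx(14.0, abs=1 / 6)

    def test_pure_exponential_no_molts(self):
        t = np.arange(0, 30, 1 / 6)
        tr = tj.AnimalTrajectory(times=t, volume=2e4 * np.exp(0.1 * t))
        ann = tj.detect_molts(tr, hatch_time=0.0)
        assert not np.isfinite(ann.molt_times).any()

    def test_simulated_animals_recovered_within_two_frames(self):
        errs = []
        for i in range(10):
            truth = syn.simulate_trajectory(syn.SimParams(seed=100 + i, noise_sd_logV=0.02))
            tr = tj.AnimalTrajectory(times=truth.times, volume=truth.observed_volume)
            ann = tj.detect_molts(tr, hatch_time=truth.hatch_time)
            errs.extend(ann.molt_times - truth.molt_times)
        frames = np.asarray(errs) / (1 / 6)
        assert np.isfinite(frames).all()
        assert np.mean(np.abs(frames) <= 2) >= 0.9

    def test_override_file_wins(self):
        truth = syn.simulate_trajectory(syn.SimParams(seed=1, noise_sd_logV=0.02))
        tr = tj.AnimalTrajectory(times=truth.times, volume=truth.observed_volume)
        ann = tj.detect_molts(tr, hatch_time=0.0, override={"M2": 19.5})
        assert ann.molt_times[1] == 19.5 and ann.method == "override"

    def test_molt_times_strictly_ordered(self):
        truth = syn.simulate_trajectory(syn.SimParams(seed=2, noise_sd_logV=0.02))
        tr = tj.AnimalTrajectory(times=truth.times, volume=truth.observed_volume)
        ann = tj.detect_molts(tr, hatch_time=0.0)
        finite = ann.molt_times[np.isfinite(ann.molt_times)]
        assert np.all(np.diff(finite) > 0)


class TestBoundaryVolume:
    def test_linear_volume_reproduced_exactly(self):
        t = np.arange(0, 10, 1 / 6)
        v = 1e4 + 500.0 * t
        tr = tj.AnimalTrajectory(times=t, volume=v)
        fit, flagged = tj.boundary_volume(tr, 5.0, side="before")
        assert fit == pytest.approx(1e4 + 2500.0, abs=1e-6)
        assert not flagged

    def test_default_uses_ten_points(self):
        import inspect

        assert inspect.signature(tj.boundary_volume).parameters["n"].default == 10

    def test_spike_shifts_estimate_by_ols_leverage(self):
        t = np.arange(30) / 6.0
        v = 2e4 + 300.0 * t
        tr = tj.AnimalTrajectory(times=t, volume=v.copy())
        event = t[19]
        base, _ = tj.boundary_volume(tr, event, side="before")
        delta = 5e3
        spiked = v.copy()
        spiked[15] += delta
        tr2 = tj.AnimalTrajectory(times=t, volume=spiked)
        shifted, _ = tj.boundary_volume(tr2, event, side="before")
        # closed-form OLS perturbation: prediction at x0 moves by
        # delta * (1/n + (x_j - xbar)(x0 - xbar)/Sxx)
        window = t[10:20]
        xbar = window.mean()
        sxx = np.sum((window - xbar) ** 2)
        lever = 1 / 10 + (t[15] - xbar) * (event - xbar) / sxx
        assert shifted - base == pytest.approx(delta * lever, rel=1e-9)

    def test_too_few_points_missing(self):
        tr = tj.AnimalTrajectory(times=np.arange(2.0), volume=np.array([1.0, 2.0]))
        fit, flagged = tj.boundary_volume(tr, 1.0, side="before")
        assert np.isnan(fit) and flagged


class TestGrowthRates:
    def test_exact_exponential_recovered(self):
        t = np.arange(0, 12, 1 / 6)
        tr = tj.AnimalTrajectory(times=t, volume=3e4 * np.exp(0.05 * t))
        g = tj.specific_growth_rate(tr)
        assert np.nanmax(np.abs(g - 0.05)) / 0.05 < 1e-6

    def test_constant_volume_zero_rate(self):
        t = np.arange(0, 10, 1 / 6)
        tr = tj.AnimalTrajectory(times=t, volume=np.full(t.size, 5e4))
        g = tj.specific_growth_rate(tr)
        assert np.nanmax(np.abs(g)) < 1e-12

    def test_two_slope_plateaus_recovered(self):
        truth = syn.simulate_trajectory(syn.SimParams(seed=5, noise_sd_logV=0.0))
        tr = tj.AnimalTrajectory(times=truth.times, volume=truth.observed_volume)
        g = tj.specific_growth_rate(tr)
        # mid-L2: away from transitions the rate matches the stage slope
        sel = (truth.times > 14.5) & (truth.times < 17.5)
        assert np.nanmedian(g[sel]) == pytest.approx(0.12, rel=0.02)

    def test_absolute_rate_on_linear_volume(self):
        t = np.arange(0, 10, 1 / 6)
        tr = tj.AnimalTrajectory(times=t, volume=1e4 + 600.0 * t)
        dv = tj.absolute_growth_rate(tr)
        assert np.nanmax(np.abs(dv - 600.0)) < 1e-6


class TestWindowedSummary:
    def test_exact_exponential_slope(self):
        t = np.arange(0, 12, 1 / 6)
        tr = tj.AnimalTrajectory(
            times=t, volume=3e4 * np.exp(0.08 * t), concentration=np.full(t.size, 50.0)
        )
        g, c = tj.windowed_summary(tr)
        assert g == pytest.approx(0.08, rel=1e-6)
        assert c == pytest.approx(50.0)

    def test_robust_to_gross_outliers(self):
        rng = np.random.default_rng(8)
        t = np.arange(0, 12, 1 / 6)
        v = 3e4 * np.exp(0.08 * t)
        idx = rng.choice(t.size, size=t.size // 10, replace=False)
        v[idx] *= 2.0
        tr = tj.AnimalTrajectory(times=t, volume=v)
        g, _ = tj.windowed_summary(tr)
        assert g == pytest.approx(0.08, rel=0.05)

    def test_default_window_center_and_width(self):
        cfg = tj.AnalysisConfig()
        assert cfg.summary_center_h == 4.3
        assert cfg.summary_halfwidth_h * 2 == pytest.approx(3.7)

    def test_sparse_window_missing(self):
        t = np.arange(0, 12, 3.0)
        tr = tj.AnimalTrajectory(times=t, volume=np.exp(t))
        g, _ = tj.windowed_summary(tr)
        assert np.isnan(g)


class TestExcludeOutliers:
    def test_all_equal_none_dropped(self):
        vals, keep = tj.exclude_outliers(np.full(10, 3.3))
        assert keep.all()

    def test_planted_outlier_dropped(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.standard_normal(100), [10.0]])
        vals, keep = tj.exclude_outliers(x, k=3)
        assert not keep[-1]
        assert keep[:-1].all()

    def test_infinite_k_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        vals, keep = tj.exclude_outliers(x, k=np.inf)
        assert keep.all()


class TestRescaleStages:
    def test_one_stage_plus_extension_is_120_points(self):
        t = np.arange(0, 20, 1 / 6)
        v = np.exp(0.1 * t)
        out = tj.rescale_stages(t, v, np.array([0.0, 12.0]), k=100, extend=0.2)
        assert out.progression.size == 120
        assert out.progression[99] == pytest.approx(100.0)
        assert out.progression[-1] == pytest.approx(120.0)

    def test_constant_signal_constant_on_grid(self):
        t = np.arange(0, 30, 1 / 6)
        out = tj.rescale_stages(t, np.full(t.size, 7.0), np.array([0.0, 10.0, 20.0]))
        assert np.allclose(out.values, 7.0)

    def test_duration_invariance_for_shape_identical_trajectories(self):
        def traj(duration):
            t = np.arange(0, duration + 5, 1e-3)
            frac = np.clip(t / duration, 0, 1)
            return t, np.sin(2 * np.pi * frac) + 2.0

        t1, v1 = traj(10.0)
        t2, v2 = traj(14.0)
        a = tj.rescale_stages(t1, v1, np.array([0.0, 10.0]), extend=0.0)
        b = tj.rescale_stages(t2, v2, np.array([0.0, 14.0]), extend=0.0)
        assert np.abs(a.values - b.values).max() < 1e-6

    def test_missing_boundary_stage_omitted(self):
        t = np.arange(0, 30, 1 / 6)
        out = tj.rescale_stages(t, np.exp(0.05 * t), np.array([0.0, 10.0, np.nan]), extend=0.0)
        assert out.stages_present.tolist() == [True, False]

    def test_value_scaling_by_duration(self):
        t = np.arange(0, 30, 1 / 6)
        out = tj.rescale_stages(
            t, np.full(t.size, 2.0), np.array([0.0, 10.0]), extend=0.0,
            scale_values_by_duration=True,
        )
        assert np.allclose(out.values, 20.0)
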