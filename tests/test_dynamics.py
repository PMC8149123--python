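"""Trace alignment, rolling rates, phase rules, exponential growth fitting."""
import numpy as np
import pandas as pd
import pytest

from capdyn.dynamics import (AlignedTrace, align_and_normalize, classify_phases,
                             fit_expansion_exponential, fit_growth_curve,
                             fold_change, rolling_expansion_rate)
from capdyn.errors import (AlignmentError, NormalizationError, ParameterError)
from capdyn.synthetic import SceneConfig, simulate_cap_movie, truth_track

# the expansion-phase growth function reported for wild-type caps
GROWTH_A = 1.642
GROWTH_K = 0.09733


def _track_df(areas, sds=None, eccs=None, interval=5.0):
    n = len(areas)
    return pd.DataFrame({
        "frame": np.arange(n),
        "area_um2": np.asarray(areas, float),
        "mean_int": np.full(n, 100.0),
        "sd_int": np.ones(n) if sds is None else np.asarray(sds, float),
        "cy_um": np.zeros(n), "cx_um": np.zeros(n),
        "ecc": np.zeros(n) if eccs is None else np.asarray(eccs, float),
    })


def _trace(areas, interval=5.0, **kw):
    df = _track_df(areas, interval=interval, **kw)
    return align_and_normalize(df, elongation_onset=0, frame_interval_s=interval,
                               lookback_s=0.0, cap_id=0)


class TestAlignment:
    def test_constant_area_normalizes_to_one(self):
        trace = _trace(np.full(10, 42.0))
        assert np.allclose(trace.norm_area, 1.0)

    def test_exponential_track_normalizes_algebraically(self):
        g, a0, dt = 0.02, 30.0, 5.0
        t = np.arange(30) * dt
        trace = _trace(a0 * np.exp(g * t))
        assert np.allclose(trace.norm_area, np.exp(g * trace.time_s), rtol=1e-12)

    def test_anchor_matches_generator_schedule(self, default_movie):
        cfg, _, truth = default_movie
        trace = align_and_normalize(truth_track(truth, 0),
                                    truth.elongation_onset_frame,
                                    frame_interval_s=cfg.frame_interval_s)
        # elongation onset sits exactly lookback_s after the aligned origin
        assert trace.anchor_time_s == pytest.approx(180.0)
        onset_t = truth.elongation_onset_frame * cfg.frame_interval_s
        t0_scene = onset_t - 180.0
        assert trace.area_um2[0] == pytest.approx(cfg.area_at(t0_scene))

    def test_normalization_idempotent(self):
        trace = _trace(30.0 * np.exp(0.02 * np.arange(20) * 5.0))
        renorm = trace.norm_area / trace.norm_area[0]
        assert np.array_equal(renorm, trace.norm_area)

    def test_short_track_raises(self):
        df = _track_df(np.ones(5) * 10)
        with pytest.raises(AlignmentError):
            align_and_normalize(df, elongation_onset=10, frame_interval_s=5.0,
                                lookback_s=180.0)

    def test_zero_sd_at_origin_raises(self):
        df = _track_df(np.ones(8) * 10, sds=np.zeros(8))
        with pytest.raises(NormalizationError):
            align_and_normalize(df, elongation_onset=0, frame_interval_s=5.0,
                                lookback_s=0.0)


class TestRollingRate:
    def test_affine_series_gives_exact_slope(self):
        c = 0.37
        trace = _trace(50.0 + c * np.arange(40) * 5.0)
        rates = rolling_expansion_rate(trace, window_s=30.0)
        assert np.allclose(rates["rate_um2_s"], c, atol=1e-12)

    def test_constant_series_gives_zero(self):
        trace = _trace(np.full(20, 9.0))
        assert np.allclose(rolling_expansion_rate(trace)["rate_um2_s"], 0.0)

    def test_exponential_rate_matches_derivative_within_2_percent(self):
        g, a0 = 0.015, 34.0
        t = np.arange(60) * 5.0
        trace = _trace(a0 * np.exp(g * t))
        rates = rolling_expansion_rate(trace, window_s=30.0)["rate_um2_s"].to_numpy()
        interior = slice(4, -4)
        analytic = a0 * g * np.exp(g * t)
        rel = np.abs(rates[interior] - analytic[interior]) / analytic[interior]
        assert np.max(rel) <= 0.02

    def test_window_too_short_raises(self):
        trace = _trace(np.arange(10.0) + 1)
        with pytest.raises(ParameterError):
            rolling_expansion_rate(trace, window_s=4.0)


class TestPhases:
    def test_boundaries_match_generator_schedule(self):
        offsets = []
        for seed in range(6):
            cfg = SceneConfig(seed=seed)
            _, truth = simulate_cap_movie(cfg)
            trace = align_and_normalize(truth_track(truth, 0),
                                        truth.elongation_onset_frame,
                                        frame_interval_s=cfg.frame_interval_s)
            ann = classify_phases(trace)
            shift = trace.anchor_time_s - cfg.phase_starts_s["elongation"]
            for phase in ("stabilization", "elongation", "fragmentation"):
                expected = cfg.phase_starts_s[phase] + shift
                offsets.append(abs(ann.boundaries[phase] - expected)
                               / cfg.frame_interval_s)
        assert max(offsets) <= 2.0

    def test_monotone_growth_single_phase(self):
        trace = _trace(30.0 * np.exp(0.02 * np.arange(30) * 5.0))
        ann = classify_phases(trace, use_anchor=False)
        assert set(ann.labels) == {"expansion"}
        assert list(ann.boundaries) == ["expansion"]

    def test_every_point_labeled_canonical_order(self, default_movie):
        cfg, _, truth = default_movie
        trace = align_and_normalize(truth_track(truth, 1),
                                    truth.elongation_onset_frame,
                                    frame_interval_s=cfg.frame_interval_s)
        ann = classify_phases(trace)
        assert not any(lab is None for lab in ann.labels)
        order = ["expansion", "stabilization", "elongation", "fragmentation"]
        seen = [ann.labels[0]] + [b for a, b in zip(ann.labels, ann.labels[1:])
                                  if b != a]
        assert seen == [p for p in order if p in seen]

    def test_unanchored_elongation_detected_from_eccentricity(self, default_movie):
        cfg, _, truth = default_movie
        trace = align_and_normalize(truth_track(truth, 0),
                                    truth.elongation_onset_frame,
                                    frame_interval_s=cfg.frame_interval_s)
        ann = classify_phases(trace, use_anchor=False)
        assert abs(ann.boundaries["elongation"] - trace.anchor_time_s) \
            <= 2 * cfg.frame_interval_s


class TestGrowthFit:
    def test_recovers_reported_function_exactly(self):
        x = np.arange(13.0)  # 0..12 frames of 5 s = the 0-60 s window
        y = GROWTH_A * np.exp(GROWTH_K * x)
        fit = fit_growth_curve(x, y, x_unit="frame")
        assert fit.amplitude == pytest.approx(GROWTH_A, abs=1e-6)
        assert fit.rate == pytest.approx(GROWTH_K, abs=1e-6)
        assert fit.r_value == pytest.approx(1.0, abs=1e-9)
        assert fit.rss <= 1e-10

    def test_constant_data_zero_rate(self):
        fit = fit_growth_curve(np.arange(10.0), np.full(10, 3.3))
        assert fit.amplitude == pytest.approx(3.3, abs=1e-9)
        assert fit.rate == pytest.approx(0.0, abs=1e-9)

    def test_noisy_rate_recovery_within_3_percent(self, rng):
        k_true = 0.09733
        x = np.arange(13.0)
        estimates = []
        for _ in range(200):
            y = 1.642 * np.exp(k_true * x) * (1 + rng.normal(0, 0.05, x.size)).clip(0.01)
            estimates.append(fit_growth_curve(x, y).rate)
        assert abs(np.median(estimates) - k_true) / k_true <= 0.03

    def test_fit_span_and_units(self, default_movie):
        cfg, _, truth = default_movie
        trace = align_and_normalize(truth_track(truth, 0),
                                    truth.elongation_onset_frame,
                                    frame_interval_s=cfg.frame_interval_s)
        fit_frames = fit_expansion_exponential(trace, x_unit="frame")
        fit_seconds = fit_expansion_exponential(trace, x_unit="s")
        assert fit_frames.x_unit == "frame"
        # same curve, rescaled X: the rate converts by the frame interval
        assert fit_frames.rate == pytest.approx(
            fit_seconds.rate * cfg.frame_interval_s, rel=1e-6)
        # truth grows at g per second within the fitted window
        assert fit_seconds.rate == pytest.approx(cfg.growth_rate_per_s, rel=1e-6)


class TestFoldChange:
    def test_identity(self):
        trace = _trace(np.linspace(10, 20, 12))
        assert fold_change(trace, 0.0, 0.0) == 1.0

    def test_linear_doubling(self):
        trace = _trace(np.linspace(10, 20, 11))
        assert fold_change(trace, 0.0, 50.0) == pytest.approx(2.0)

    def test_default_movie_fold_near_six(self, default_movie):
        cfg, _, truth = default_movie
        fold = truth.fold_change(0, 0.0, cfg.expansion_s)
        assert 5.5 <= fold <= 6.5

    def test_out_of_range_raises(self):
        trace = _trace(np.ones(5) * 4)
        with pytest.raises(ParameterError):
            fold_change(trace, 0.0, 500.0)
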