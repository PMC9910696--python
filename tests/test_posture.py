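import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posture_ensemble import (
    MISSING,
    RECLINING,
    SITTING,
    WALKING,
    AccelSeries,
    AngleHistogram,
    EmptyInputError,
    EpochGrid,
    PostureThresholds,
    WalkingRule,
    ZeroNormError,
    build_angle_histogram,
    classify_day,
    classify_sample,
    detect_walking,
    estimate_thresholds,
    trunk_angle,
)


def _series_from_norm(norm, rate=25.0, direction=(0.0, 1.0, 0.0)):
    """Acceleration series with the given per-sample norm along one direction."""
    norm = np.asarray(norm, dtype=float)
    t = pd.Timestamp("2023-01-01") + pd.to_timedelta(np.arange(len(norm)) / rate, unit="s")
    d = np.asarray(direction) / np.linalg.norm(direction)
    df = pd.DataFrame({"t": t, "ax": norm * d[0], "ay": norm * d[1], "az": norm * d[2]})
    return AccelSeries("d", df, nominal_rate=rate)


class TestTrunkAngle:
    @pytest.mark.parametrize(
        "v,expected",
        [((0, 0, 1), 0.0), ((0, 1, 0), 90.0), ((0, -1, 0), -90.0), ((0, 0, -1), 180.0)],
    )
    def test_cardinal_directions(self, v, expected):
        assert trunk_angle(*v) == pytest.approx(expected)

    def test_zero_norm_raises(self):
        with pytest.raises(ZeroNormError):
            trunk_angle(0.0, 0.0, 0.0)

    def test_zero_norm_is_nan_in_arrays(self):
        out = trunk_angle(np.array([0.0, 0.0]), np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(90.0)

    @given(
        v=st.tuples(*[st.floats(-5, 5) for _ in range(3)]).filter(
            lambda v: np.linalg.norm(v) > 1e-3
        ),
        k=st.floats(0.01, 100),
    )
    @settings(deadline=None)
    def test_scale_invariance(self, v, k):
        ax, ay, az = v
        assert trunk_angle(k * ax, k * ay, k * az) == pytest.approx(
            trunk_angle(ax, ay, az), abs=1e-9
        )

    @given(
        v=st.tuples(*[st.floats(-5, 5) for _ in range(3)]).filter(
            lambda v: np.linalg.norm(v) > 1e-3 and abs(v[1]) > 1e-6
        )
    )
    @settings(deadline=None)
    def test_antisymmetric_in_ay_sign(self, v):
        ax, ay, az = v
        theta = trunk_angle(ax, ay, az)
        if abs(theta) not in (0.0, 180.0):
            assert trunk_angle(ax, -ay, az) == pytest.approx(-theta)


class TestClassifySample:
    @pytest.mark.parametrize(
        "theta,walking,expected",
        [
            (90.0, False, SITTING),
            (35.0, False, SITTING),  # band is inclusive
            (143.0, False, SITTING),
            (10.0, False, RECLINING),
            (170.0, False, RECLINING),
            (-90.0, False, RECLINING),
            (90.0, True, WALKING),
            (170.0, True, RECLINING),  # walking overlays only the upright state
            (10.0, True, RECLINING),
        ],
    )
    def test_examples(self, theta, walking, expected):
        assert classify_sample(theta, walking) == expected

    @given(theta=st.floats(-180, 180), walking=st.booleans())
    @settings(deadline=None)
    def test_total_function_single_label(self, theta, walking):
        assert classify_sample(theta, walking) in {RECLINING, SITTING, WALKING}

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ValueError):
            classify_sample(200.0, False)


class TestThresholdsValidation:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            PostureThresholds(prone_upright=150.0, upright_supine=100.0)


def _bruteforce_walking(series, rule):
    """Independent rule evaluation: naive local-maxima peaks, then an
    O(n^2) scan over maximal cadence-compatible runs."""
    norm = series.norms()
    rate = series.nominal_rate
    window = max(1, int(round(rule.baseline_window * rate)))
    # centered moving average with edge replication, written longhand
    padded = np.concatenate(
        [np.full(window, norm[0]), norm, np.full(window, norm[-1])]
    )
    kernel = np.ones(window) / window
    base = np.convolve(padded, kernel, mode="same")[window:-window]
    x = norm - base
    peaks = [
        i
        for i in range(1, len(x) - 1)
        if x[i] > rule.peak_threshold and x[i] > x[i - 1] and x[i] >= x[i + 1]
    ]
    t = series.seconds_from_start()
    out = np.zeros(len(x), dtype=bool)
    i = 0
    while i < len(peaks):
        j = i
        while (
            j + 1 < len(peaks)
            and rule.min_interval <= t[peaks[j + 1]] - t[peaks[j]] <= rule.max_interval
        ):
            j += 1
        if j - i + 1 >= rule.min_consecutive_steps:
            out[peaks[i] : peaks[j] + 1] = True
        i = j + 1
    return out


class TestDetectWalking:
    def test_constant_signal_no_walking(self):
        s = _series_from_norm(np.ones(250))
        assert not detect_walking(s).any()

    def test_gait_oscillation_detected(self):
        # 2 Hz steps of amplitude 0.3 g for 10 s: peaks every 0.5 s
        t = np.arange(250) / 25.0
        s = _series_from_norm(1.0 + 0.3 * np.sin(2 * np.pi * 2.0 * t))
        walking = detect_walking(s)
        # the span between first and last peak is marked
        assert walking.mean() > 0.8

    def test_isolated_peaks_too_far_apart(self):
        norm = np.ones(500)
        norm[100] = 1.5
        norm[350] = 1.5  # 10 s apart > max_interval
        s = _series_from_norm(norm)
        assert not detect_walking(s).any()

    def test_too_few_steps_not_walking(self):
        norm = np.ones(250)
        for k in range(3):  # 3 peaks < min_consecutive_steps=4
            norm[50 + 13 * k] = 1.5
        s = _series_from_norm(norm)
        assert not detect_walking(s).any()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 1000))
        norm = 1.0 + rng.normal(0, 0.08, n)
        spikes = rng.choice(n, size=int(rng.integers(5, 40)), replace=False)
        norm[spikes] += rng.uniform(0.1, 0.5, len(spikes))
        s = _series_from_norm(norm)
        rule = WalkingRule()
        assert (detect_walking(s, rule) == _bruteforce_walking(s, rule)).all()


class TestClassifyDay:
    def test_constant_supine_day_all_reclining(self):
        # 1 sample per epoch at a matching nominal rate covers the full day
        grid = EpochGrid(60)
        t = pd.Timestamp("2023-01-01") + pd.to_timedelta(np.arange(1440) * 60, unit="s")
        df = pd.DataFrame({"t": t, "ax": 0.0, "ay": 0.0, "az": 1.0})
        s = AccelSeries("d", df, nominal_rate=1 / 60)
        day = classify_day(s, grid)
        assert (day.labels == RECLINING).all()

    def test_plurality_aggregation(self):
        grid = EpochGrid(60)
        # one epoch: 7 upright samples, 3 reclining samples at 1/6 Hz
        thetas = [90.0] * 7 + [0.0] * 3
        t = pd.Timestamp("2023-01-01") + pd.to_timedelta(np.arange(10) * 6, unit="s")
        rad = np.radians(thetas)
        df = pd.DataFrame({"t": t, "ax": 0.0, "ay": np.sin(rad), "az": np.cos(rad)})
        s = AccelSeries("d", df, nominal_rate=1 / 6)
        day = classify_day(s, grid)
        assert day.labels[0] == SITTING
        assert (day.labels[1:] == MISSING).all()

    def test_empty_epochs_are_missing(self):
        grid = EpochGrid(60)
        t = pd.Timestamp("2023-01-01 00:02:00") + pd.to_timedelta(np.arange(60), unit="s")
        df = pd.DataFrame({"t": t, "ax": 0.0, "ay": 1.0, "az": 0.0})
        s = AccelSeries("d", df, nominal_rate=1.0)
        day = classify_day(s, grid)
        assert day.labels[0] == MISSING
        assert day.labels[2] == SITTING


class TestAngleHistogram:
    def test_point_mass(self):
        h = build_angle_histogram(np.zeros(100), bin_width=1.0)
        assert h.counts.sum() == 100
        assert (h.counts > 0).sum() == 1

    def test_bin_count_arithmetic(self):
        h = build_angle_histogram(np.array([0.0]), bin_width=1.0)
        assert len(h.counts) == 360

    @given(angles=st.lists(st.floats(-179.9, 179.9), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=25)
    def test_count_conservation(self, angles):
        h = build_angle_histogram(np.array(angles), bin_width=5.0)
        assert h.counts.sum() == len(angles)

    def test_no_data_is_empty_input(self):
        with pytest.raises(EmptyInputError):
            build_angle_histogram(np.array([np.nan]))


class TestEstimateThresholds:
    @staticmethod
    def _triangular_counts(centers, mode, half_width, height=100.0):
        return np.maximum(0.0, height * (1 - np.abs(centers - mode) / half_width))

    def test_recovers_deep_valleys(self):
        # trimodal: modes at 10/90/170 with exact zero plateaus around 40 and 140
        edges = np.linspace(-180, 180, 361)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = (
            self._triangular_counts(centers, 10, 28)
            + self._triangular_counts(centers, 90, 48)
            + self._triangular_counts(centers, 170, 28)
        )
        hist = AngleHistogram(bin_edges=edges, counts=counts)
        th = estimate_thresholds(hist)
        assert th.prone_upright == pytest.approx(40.0, abs=1.0)
        assert th.upright_supine == pytest.approx(140.0, abs=1.0)

    def test_unique_zero_bin(self):
        edges = np.linspace(-180, 180, 361)
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.full(360, 50.0)
        counts[np.argmin(np.abs(centers - 35.0))] = 0.0
        hist = AngleHistogram(bin_edges=edges, counts=counts)
        th = estimate_thresholds(hist, smooth_window=1)
        assert th.prone_upright == pytest.approx(35.0, abs=0.5)

    def test_flat_range_warns_and_uses_midpoint(self):
        edges = np.linspace(-180, 180, 361)
        counts = np.full(360, 10.0)
        hist = AngleHistogram(bin_edges=edges, counts=counts)
        with pytest.warns(UserWarning):
            th = estimate_thresholds(hist)
        assert th.prone_upright == pytest.approx((15 + 60) / 2)
        assert th.upright_supine == pytest.approx((120 + 165) / 2)

    @pytest.mark.parametrize("boundaries", [(35.0, 143.0), (40.0, 140.0), (30.0, 150.0)])
    def test_recovery_from_separated_angle_regimes(self, boundaries):
        # angle regimes separated by +-5 deg gaps at (L, U): the estimated
        # valleys must land within +-5 deg of the true separators
        L, U = boundaries
        rng = np.random.default_rng(42)
        low = rng.uniform(L - 30, L - 5, 4000)
        mid = rng.uniform(L + 5, U - 5, 6000)
        high = rng.uniform(U + 5, U + 25, 2000)
        hist = build_angle_histogram(np.concatenate([low, mid, high]), bin_width=1.0)
        th = estimate_thresholds(
            hist, search_low=(L - 15, L + 15), search_high=(U - 15, U + 15)
        )
        assert abs(th.prone_upright - L) <= 5.0
        assert abs(th.upright_supine - U) <= 5.0
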