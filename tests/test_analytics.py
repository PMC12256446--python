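import numpy as np
import pytest

from okrloop.analytics import (
    AnalyticsError,
    TimeBin,
    default_tau_grid,
    delta_series,
    detect_saccades_disagreement,
    detect_saccades_velocity,
    disagreement_curve,
    nea,
    optimal_threshold,
    parity_ratio,
    threshold_filter,
)
from okrloop.eyetrack import EyeAngleSeries
from okrloop.larva import VirtualLarvaParams, simulate_trace
from okrloop.stimulus import GratingParams

from conftest import make_bins


def series_from(theta, dt=0.1):
    theta = np.asarray(theta, dtype=float)
    return EyeAngleSeries(
        t=dt * np.arange(len(theta)), theta_left=theta, theta_right=theta.copy()
    )


# ---------------------------------------------------------------------- Eq. 1


class TestThresholdFilter:
    def test_hand_example(self):
        np.testing.assert_allclose(
            threshold_filter(np.array([0.5, -2.0, 3.0]), 1.0), [0.0, -2.0, 3.0]
        )

    def test_zero_threshold_keeps_all_nonzero(self):
        d = np.array([0.3, -0.7, 2.0, 0.0])
        np.testing.assert_allclose(threshold_filter(d, 0.0), d)

    def test_all_suppressed(self):
        np.testing.assert_allclose(threshold_filter(np.array([1.0, -1.0]), 5.0), [0.0, 0.0])

    def test_idempotent(self, rng):
        d = rng.normal(0, 2, 100)
        once = threshold_filter(d, 1.5)
        np.testing.assert_allclose(threshold_filter(once, 1.5), once)

    def test_monotone_in_tau(self, rng):
        d = rng.normal(0, 2, 200)
        counts = [np.count_nonzero(threshold_filter(d, tau)) for tau in np.linspace(0, 5, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_nan_gaps_preserved(self):
        out = threshold_filter(np.array([np.nan, 2.0]), 1.0)
        assert np.isnan(out[0]) and out[1] == 2.0


# ---------------------------------------------------------------------- Eq. 2


def dbin(tb, tbn, omega):
    return TimeBin(tb, tbn, GratingParams(omega=omega))


class TestParityRatio:
    def test_hand_count(self):
        filt = np.array([+1.0, +2.0, -1.0, +3.0])
        t = np.array([0.0, 0.1, 0.2, 0.3])
        assert parity_ratio(filt, t, dbin(0.0, 1.0, +30.0)) == pytest.approx(3.0)

    def test_all_zero_is_undefined(self):
        filt = np.zeros(4)
        t = np.arange(4) * 0.1
        assert np.isnan(parity_ratio(filt, t, dbin(0.0, 1.0, +30.0)))

    def test_infinite_when_no_misaligned(self):
        filt = np.array([1.0, 2.0, 3.0])
        t = np.arange(3) * 0.1
        assert np.isposinf(parity_ratio(filt, t, dbin(0.0, 1.0, +30.0)))

    def test_mirror_symmetry(self, rng):
        filt = rng.normal(0, 1, 50)
        t = np.arange(50) * 0.1
        s_ccw = parity_ratio(filt, t, dbin(0.0, 5.0, +30.0))
        s_cw = parity_ratio(-filt, t, dbin(0.0, 5.0, -30.0))
        assert s_ccw == pytest.approx(s_cw)

    def test_blank_bin_rejected(self):
        with pytest.raises(AnalyticsError):
            parity_ratio(np.ones(3), np.arange(3) * 0.1, TimeBin(0, 1, GratingParams(blank=True)))


# ------------------------------------------------------- optimal threshold


def brute_force_tau(series, bins, tau_grid, eye, mode):
    """Independent pure-python grid search (aligned vs misaligned counts)."""
    theta = list(series.theta(eye))
    times = list(series.t)
    best_tau, best_s = None, None
    for tau in tau_grid:
        good = 0
        bad = 0
        for i in range(1, len(theta)):
            d = theta[i] - theta[i - 1]
            if d != d or abs(d) <= tau or d == 0.0:
                continue
            for b in bins:
                if b.stimulus.blank or b.stimulus.omega == 0:
                    continue
                if b.tb <= times[i - 1] < b.tbn:
                    aligned = (d > 0) == (b.stimulus.omega > 0)
                    if mode == "parity":
                        good, bad = (good + 1, bad) if aligned else (good, bad + 1)
                    else:  # disagreement mode
                        good, bad = (good + 1, bad) if not aligned else (good, bad + 1)
                    break
        if bad == 0:
            s = float("inf") if good > 0 else float("nan")
        else:
            s = good / bad
        if s == s and (best_s is None or best_s != best_s or s > best_s):
            if not (best_s == float("inf")):
                best_s, best_tau = s, tau
    if best_tau is None:
        best_tau = tau_grid[0]
    return best_tau


class TestOptimalThreshold:
    def test_noiseless_following_is_infinite_parity(self, alternating_bins):
        p = VirtualLarvaParams(jitter_sd=0.0, latency=0.0, saccade_trigger=1e6, seed=0)
        trace = simulate_trace(p, alternating_bins)
        curves = optimal_threshold(trace.series, alternating_bins, tau_grid=np.arange(0.1, 1.0, 0.1))
        # every aligned delta is 1.2 deg/frame, none misaligned below that
        assert np.isposinf(curves["left"].S[0])
        assert curves["left"].tau_opt == pytest.approx(0.1)

    def test_threshold_suppresses_jitter(self, alternating_bins):
        p = VirtualLarvaParams(jitter_sd=0.4, latency=0.0, seed=3)
        trace = simulate_trace(p, alternating_bins)
        curves = optimal_threshold(trace.series, alternating_bins)
        c = curves["left"]
        assert c.S[list(c.tau_grid).index(c.tau_opt)] >= c.S[0] or np.isposinf(c.S[0])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed, alternating_bins):
        p = VirtualLarvaParams(jitter_sd=0.8, latency=0.0, seed=seed)
        trace = simulate_trace(p, alternating_bins)
        grid = default_tau_grid()
        curves = optimal_threshold(trace.series, alternating_bins, tau_grid=grid)
        for eye in ("left", "right"):
            oracle = brute_force_tau(trace.series, alternating_bins, list(grid), eye, "parity")
            assert curves[eye].tau_opt == oracle

    def test_no_directed_bins_rejected(self):
        s = series_from(np.zeros(10))
        with pytest.raises(AnalyticsError):
            optimal_threshold(s, [TimeBin(0, 1, GratingParams(blank=True))])


# ------------------------------------------------------------------- Eq. 3


class TestNea:
    def test_hand_summed_two_bins(self):
        # bin 1 deltas: 1+1 = 2; bin 2 deltas: 2+2 = 4
        theta = np.array([0.0, 1.0, 2.0, 2.0, 4.0, 6.0])
        s = series_from(theta)
        bins = make_bins(
            [(0.0, 0.25, 30.0, False, "b1"), (0.25, 0.55, 30.0, False, "b2")]
        )
        table = nea(s, bins)
        np.testing.assert_allclose(table["B"], [2.0, 4.0])
        np.testing.assert_allclose(table["NEA"], [0.5, 1.0])

    def test_single_bin_self_normalizes(self):
        s = series_from([0.0, 2.0, 1.0])
        table = nea(s, make_bins([(0.0, 0.25, 30.0, False, "only")]))
        assert table["NEA"].iloc[0] == 1.0

    def test_constant_trace_flagged(self):
        s = series_from(np.full(10, 5.0))
        table = nea(s, make_bins([(0.0, 0.5, 30.0, False, "a"), (0.5, 1.0, -30.0, False, "b")]))
        assert table["flagged"].all()
        assert table["NEA"].isna().all()

    def test_normalization_invariants(self, rng):
        for _ in range(10):
            s = series_from(np.cumsum(rng.normal(0, 1, 60)))
            bins = make_bins(
                [(0.0, 2.0, 30.0, False, "a"), (2.0, 4.0, -30.0, False, "b"), (4.0, 6.0, 0.0, True, "B")]
            )
            table = nea(s, bins)
            assert table["NEA"].max() == pytest.approx(1.0)
            assert ((table["NEA"] >= 0) & (table["NEA"] <= 1.0 + 1e-12)).all()

    def test_shared_label_bins_are_summed(self):
        theta = np.array([0.0, 1.0, 1.0, 3.0, 3.0, 4.0])
        s = series_from(theta)
        bins = make_bins(
            [(0.0, 0.15, 0.0, True, "B"), (0.15, 0.35, 30.0, False, "d"), (0.35, 0.55, 0.0, True, "B")]
        )
        table = nea(s, bins)
        assert set(table["bin"]) == {"B", "d"}
        assert len(table) == 2
        # both-endpoint rule: B gets the first delta (1) plus the last (1)
        brow = table.set_index("bin").loc["B"]
        assert brow["B"] == 2.0


# ---------------------------------------------------------------- saccades


class TestVelocityDetector:
    def make_trace_with_resets(self, reset_frames, drift=0.05, n=100):
        theta = np.cumsum(np.full(n, drift))
        for f in reset_frames:
            theta[f:] -= 2.0  # 20 deg/s single-frame reset at 10 Hz
        return series_from(theta)

    def test_single_programmed_reset(self):
        s = self.make_trace_with_resets([50])
        ev = detect_saccades_velocity(s, v_thresh=3.0)
        assert ev.count == 1
        assert ev.times[0] == pytest.approx(5.0, abs=0.15)

    def test_flat_trace(self):
        ev = detect_saccades_velocity(series_from(np.zeros(50)), v_thresh=3.0)
        assert ev.count == 0

    def test_threshold_above_max_velocity(self):
        s = self.make_trace_with_resets([30, 60])
        ev = detect_saccades_velocity(s, v_thresh=50.0)
        assert ev.count == 0

    def test_count_non_increasing_in_threshold(self):
        s = self.make_trace_with_resets([20, 40, 60, 80])
        counts = [
            detect_saccades_velocity(s, v_thresh=v).count for v in np.linspace(0.5, 30, 15)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_merged_consecutive_frames(self):
        theta = np.zeros(40)
        theta[20:] = 5.0
        theta[21:] = 9.0  # two consecutive supra-threshold steps
        ev = detect_saccades_velocity(series_from(theta), v_thresh=3.0)
        assert ev.count == 1


class TestDisagreementDetector:
    def test_recovers_programmed_saccade_count(self, alternating_bins):
        p = VirtualLarvaParams(jitter_sd=0.1, latency=0.0, saccade_trigger=8.0, seed=5)
        trace = simulate_trace(p, alternating_bins)
        k = len(trace.saccade_times_left)
        assert k > 0
        ev = detect_saccades_disagreement(trace.series, alternating_bins, eye="left")
        assert ev.count == k

    def test_no_saccades_detects_none(self, alternating_bins):
        # excursion limit far above anything the schedule can drive
        p = VirtualLarvaParams(jitter_sd=0.0, latency=0.0, saccade_trigger=1e6, seed=1)
        trace = simulate_trace(p, alternating_bins)
        assert len(trace.saccade_times_left) == 0
        ev = detect_saccades_disagreement(trace.series, alternating_bins, eye="left")
        assert ev.count == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_matches_brute_force(self, seed, alternating_bins):
        p = VirtualLarvaParams(jitter_sd=0.5, latency=0.0, saccade_trigger=8.0, seed=seed)
        trace = simulate_trace(p, alternating_bins)
        grid = default_tau_grid()
        curve = disagreement_curve(trace.series, alternating_bins, eye="left", tau_grid=grid)
        oracle = brute_force_tau(trace.series, alternating_bins, list(grid), "left", "disagree")
        assert curve.tau_opt == oracle


class TestDeltaSeries:
    def test_deltas_match_plain_differencing(self, rng):
        theta = np.cumsum(rng.normal(0, 1, 50))
        s = series_from(theta)
        t, d = delta_series(s, "left")
        np.testing.assert_allclose(d, np.diff(theta))
        np.testing.assert_allclose(t, s.t[1:])

    def test_gap_propagates_to_both_neighbor_deltas(self):
        theta = np.array([0.0, 1.0, np.nan, 3.0, 4.0])
        s = series_from(theta)
        _, d = delta_series(s, "left")
        assert np.isnan(d[1]) and np.isnan(d[2])
        assert d[0] == 1.0 and d[3] == 1.0
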