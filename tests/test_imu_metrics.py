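"""Kinematic metric operations: magnitudes, z-scores, peaks, METs, energy."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kinwell import (
    AccelSeries,
    DegenerateSignalError,
    InputError,
    PeakDetectionConfig,
    action_count,
    detect_peaks,
    energy_expenditure,
    frame_magnitude,
    magnitude,
    max_acceleration,
    mets_from_rms,
    rms_acceleration,
    session_metrics,
    zscore_series,
)
from kinwell.synthetic import SensorFrame

from oracles import brute_force_peaks


def _series(values, dt_s=1.0):
    values = np.asarray(values, dtype=float)
    return AccelSeries(values=values, duration_h=len(values) * dt_s / 3600.0)


class TestMagnitude:
    @pytest.mark.parametrize(
        "ax, ay, az, expected",
        [
            ([3.0], [4.0], [0.0], [5.0]),
            ([0.0], [0.0], [0.0], [0.0]),
            ([1.0], [1.0], [1.0], [np.sqrt(3.0)]),
        ],
    )
    def test_euclidean_norm(self, ax, ay, az, expected):
        series = magnitude(ax, ay, az, duration_s=1.0)
        assert series.values == pytest.approx(expected)

    def test_duration_from_timestamps(self):
        t = np.arange(100) / 50.0
        series = magnitude(np.ones(100), np.zeros(100), np.zeros(100), timestamps=t)
        assert series.duration_h * 3600 == pytest.approx(2.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(InputError):
            magnitude([1.0, 2.0], [1.0], [1.0, 2.0], duration_s=1.0)


class TestZScore:
    def test_direct_substitution(self):
        # a point at 12 in a series with mean 10 and population sigma 2
        series = _series([8.0, 10.0, 12.0, 10.0, 8.0, 12.0])
        z = zscore_series(series)
        mu, sigma = np.mean(series.values), np.std(series.values)
        assert z[2] == pytest.approx((12.0 - mu) / sigma)

    def test_spike_series_hand_computed(self):
        # [0,0,10,0,0]: mean 2, population sigma 4 -> z at spike = 2.0
        z = zscore_series(_series([0, 0, 10, 0, 0]))
        assert z[2] == pytest.approx(2.0)
        assert z[0] == pytest.approx(-0.5)

    def test_value_at_mean_scores_zero(self):
        series = _series([1.0, 2.0, 3.0])
        assert zscore_series(series)[1] == pytest.approx(0.0)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            zscore_series(_series([5.0, 5.0, 5.0]))

    def test_rolling_window_mode(self):
        cfg = PeakDetectionConfig(windowing="rolling", rolling_window_s=3.0)
        z = zscore_series(_series([0, 0, 10, 0, 0]), cfg)
        assert z.shape == (5,)
        assert z[2] > 0


class TestDetectPeaks:
    def test_single_spike(self):
        peaks = detect_peaks(_series([0, 0, 10, 0, 0]), PeakDetectionConfig(min_separation_s=0))
        assert peaks.tolist() == [2]

    def test_constant_series_yields_no_peaks(self):
        assert detect_peaks(_series([3.0] * 10)).size == 0

    def test_close_spikes_keep_first(self):
        # identical spikes 0.1 s apart at 50 Hz; 0.25 s separation keeps the first
        values = np.zeros(50)
        values[[10, 15]] = 10.0
        series = _series(values, dt_s=0.02)
        cfg = PeakDetectionConfig(min_separation_s=0.25)
        assert detect_peaks(series, cfg).tolist() == [10]

    def test_endpoints_never_peaks(self):
        peaks = detect_peaks(_series([10, 0, 0, 0, 10]), PeakDetectionConfig(min_separation_s=0))
        assert peaks.size == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 2000))
        values = np.abs(rng.normal(1.0, 0.5, n))
        spikes = rng.choice(n, size=max(1, n // 50), replace=False)
        values[spikes] += rng.uniform(2, 10, size=len(spikes))
        dt = 0.02
        series = _series(values, dt_s=dt)
        cfg = PeakDetectionConfig(z_threshold=2.0, min_separation_s=0.1)
        got = detect_peaks(series, cfg).tolist()
        expected = brute_force_peaks(values.tolist(), 2.0, 0.1, dt)
        assert got == expected

    @given(st.integers(0, 10_000), st.floats(0.1, 50.0))
    def test_scale_invariance(self, seed, k):
        rng = np.random.default_rng(seed)
        values = np.abs(rng.normal(1.0, 0.5, 200))
        values[rng.integers(1, 199)] += 8.0
        a = _series(values, dt_s=0.02)
        b = _series(k * values, dt_s=0.02)
        np.testing.assert_allclose(zscore_series(a), zscore_series(b), atol=1e-9)
        assert detect_peaks(a).tolist() == detect_peaks(b).tolist()
        assert action_count(detect_peaks(a), a.n) == action_count(detect_peaks(b), b.n)


class TestScalarMetrics:
    @pytest.mark.parametrize(
        "peaks, n, expected", [(1, 5, 0.2), (0, 7, 0.0), (300, 30_000, 0.01)]
    )
    def test_action_count(self, peaks, n, expected):
        assert action_count(np.arange(peaks), n) == pytest.approx(expected)

    def test_action_count_rejects_empty(self):
        with pytest.raises(InputError):
            action_count(np.array([]), 0)

    def test_max_acceleration(self):
        assert max_acceleration(_series([1.2, 3.4, 2.2])) == pytest.approx(3.4)
        assert max_acceleration(_series([7.0])) == pytest.approx(7.0)

    @pytest.mark.parametrize(
        "values, expected",
        [([3.0, 4.0], np.sqrt(12.5)), ([5.0, 5.0, 5.0], 5.0), ([0.0, 0.0, 0.0], 0.0)],
    )
    def test_rms_acceleration(self, values, expected):
        assert rms_acceleration(_series(values)) == pytest.approx(expected)

    @given(st.integers(0, 1000))
    def test_max_at_least_rms(self, seed):
        rng = np.random.default_rng(seed)
        series = _series(np.abs(rng.normal(2, 3, int(rng.integers(1, 500)))))
        assert max_acceleration(series) >= rms_acceleration(series) - 1e-12

    @pytest.mark.parametrize(
        "rms, clamped, raw",
        [(10.0, 3.0, 3.0), (12.0, 6.6, 6.6), (5.0, 0.0, -6.0)],
    )
    def test_mets_linear_with_clamp(self, rms, clamped, raw):
        m, m_raw = mets_from_rms(rms)
        assert m == pytest.approx(clamped)
        assert m_raw == pytest.approx(raw)

    def test_mets_monotone_in_rms(self):
        grid = np.linspace(0, 20, 100)
        vals = [mets_from_rms(r)[0] for r in grid]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize(
        "mets, d, w, expected", [(3.0, 0.5, 60.0, 94.5), (0.0, 2.0, 80.0, 0.0), (1.0, 1.0, 1.0, 1.05)]
    )
    def test_energy_expenditure(self, mets, d, w, expected):
        assert energy_expenditure(mets, d, w) == pytest.approx(expected)

    def test_energy_linear_in_each_argument(self):
        base = energy_expenditure(2.0, 1.5, 70.0)
        assert energy_expenditure(4.0, 1.5, 70.0) == pytest.approx(2 * base)
        assert energy_expenditure(2.0, 3.0, 70.0) == pytest.approx(2 * base)
        assert energy_expenditure(2.0, 1.5, 140.0) == pytest.approx(2 * base)

    def test_negative_arguments_rejected(self):
        with pytest.raises(InputError):
            mets_from_rms(-1.0)
        with pytest.raises(InputError):
            energy_expenditure(-1.0, 1.0, 60.0)


def _frame(site, az_values, pid="P01", week=1, game="g"):
    n = len(az_values)
    t = np.arange(n) / 25.0
    return SensorFrame(
        participant_id=pid, session_week=week, game=game, sensor_site=site,
        timestamps=t, ax=np.zeros(n), ay=np.zeros(n), az=np.asarray(az_values, float),
    )


class TestSessionMetrics:
    def test_single_sensor_aggregate_identity(self):
        az = np.abs(np.random.default_rng(0).normal(9.8, 0.5, 100))
        frames = [_frame("waist_L4", az)]
        m = session_metrics(frames, weight_kg=70)
        agg, single = m["AGGREGATE"], m["waist_L4"]
        assert agg.action_count == pytest.approx(single.action_count)
        assert agg.max_acceleration == pytest.approx(single.max_acceleration)
        assert agg.rms_acceleration == pytest.approx(single.rms_acceleration)
        assert agg.energy_kcal == pytest.approx(single.energy_kcal)

    def test_aggregate_max_is_cross_sensor_max(self):
        rng = np.random.default_rng(1)
        a = np.abs(rng.normal(2, 0.3, 100))
        a[50] = 3.0
        b = np.abs(rng.normal(2, 0.3, 100))
        b[60] = 5.0
        m = session_metrics([_frame("foot_L", a), _frame("foot_R", b)])
        assert m["AGGREGATE"].max_acceleration == pytest.approx(5.0)

    def test_identical_sensors_symmetric(self):
        az = np.abs(np.random.default_rng(2).normal(9.8, 0.5, 200))
        sites = ["forearm_L", "forearm_R", "waist_L4", "foot_L", "foot_R"]
        m = session_metrics([_frame(s, az) for s in sites])
        agg = m["AGGREGATE"]
        for s in sites:
            assert m[s].rms_acceleration == pytest.approx(agg.rms_acceleration)
            assert m[s].action_count == pytest.approx(agg.action_count)

    def test_mixed_identities_rejected(self):
        az = np.ones(10) * 9.8
        az[5] = 15.0
        with pytest.raises(InputError):
            session_metrics([_frame("foot_L", az, pid="P01"), _frame("foot_R", az, pid="P02")])


def test_peak_counts_recover_simulated_event_rate():
    """At the default event rate and noise, detected peaks per full-length
    segment stay within 10% of the generator's true event count."""
    from kinwell import CohortConfig, simulate_imu_session

    cfg = CohortConfig(seed=42)
    frames = simulate_imu_session(cfg, "P01", 1, cfg.games[0], group="mentally_well")
    true_n = len(frames[0].event_times)
    for f in frames[:2]:
        detected = len(detect_peaks(frame_magnitude(f)))
        assert abs(detected - true_n) / true_n < 0.10
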