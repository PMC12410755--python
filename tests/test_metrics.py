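"""Firing statistics, burst detection (with brute-force oracle), drug
time courses, percent changes and LFP propagation speed."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdmea.chip import ChipGeometry, electrode_position
from hdmea.metrics import (
    burst_isi_iqr,
    detect_bursts,
    drug_timecourse,
    lfp_propagation_speed,
    percent_change,
    unit_metrics,
)
from hdmea.synth import GroundTruth, apply_pharmacology, generate_trains, \
    synthesize_lfp_wave


def brute_force_bursts(times, min_spikes=5, max_isi_ms=100.0):
    """Independent oracle: enumerate every window [i, j] and keep windows
    that satisfy the burst rule and cannot be extended on either side."""
    times = np.sort(np.asarray(times, float))
    n = times.size
    max_isi = max_isi_ms * 1e-3
    found = []
    for i in range(n):
        for j in range(i + min_spikes - 1, n):
            isis = np.diff(times[i : j + 1])
            tol = max_isi * (1 + 1e-9) + 1e-12  # same edge convention
            if np.any(isis > tol):
                break
            left_ext = i > 0 and times[i] - times[i - 1] <= tol
            right_ext = j < n - 1 and times[j + 1] - times[j] <= tol
            if not left_ext and not right_ext:
                found.append((i, j))
    return found


class TestUnitMetrics:
    def test_mean_firing_rate(self):
        m = unit_metrics(np.linspace(0, 49.5, 100), (0.0, 50.0))
        assert m.mfr_hz == pytest.approx(2.0)

    def test_regular_train_has_zero_variability(self):
        m = unit_metrics(np.arange(0, 10, 0.1), (0.0, 10.0))
        assert m.cv == pytest.approx(0.0, abs=1e-9)
        assert m.cv2 == pytest.approx(0.0, abs=1e-9)

    def test_poisson_train_near_unit_cv_and_cv2(self, rng):
        times = np.sort(rng.uniform(0, 1000, 10_000))
        m = unit_metrics(times, (0.0, 1000.0))
        assert m.cv == pytest.approx(1.0, abs=0.05)
        assert m.cv2 == pytest.approx(1.0, abs=0.05)

    def test_too_few_spikes_give_missing_variability(self):
        m = unit_metrics(np.array([1.0, 2.0]), (0.0, 10.0))
        assert m.mfr_hz == pytest.approx(0.2)
        assert np.isnan(m.cv) and np.isnan(m.cv2)

    def test_cv2_of_alternating_isis_exact(self):
        # alternating ISIs a, b -> cv2 = 2|a-b|/(a+b) exactly
        a, b = 0.02, 0.08
        isis = np.tile([a, b], 20)
        times = np.concatenate([[0.0], np.cumsum(isis)])
        m = unit_metrics(times, (0.0, times[-1] + 1.0))
        assert m.cv2 == pytest.approx(2 * abs(a - b) / (a + b), rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-4, 2.0), min_size=3, max_size=50))
    def test_cv2_bounded_in_zero_two(self, isis):
        times = np.concatenate([[0.0], np.cumsum(isis)])
        m = unit_metrics(times, (0.0, float(times[-1]) + 1.0))
        assert 0.0 <= m.cv2 <= 2.0


class TestDetectBursts:
    def test_minimal_burst_at_rule_boundary(self):
        times = np.arange(5) * 0.05  # 5 spikes, ISIs 50 ms
        bs = detect_bursts(times, 60.0)
        assert bs.n_bursts == 1
        assert bs.bursts[0].n_spikes == 5

    def test_isi_exactly_100ms_is_inclusive(self):
        times = np.arange(5) * 0.1
        assert detect_bursts(times, 60.0).n_bursts == 1

    def test_four_spikes_no_burst(self):
        assert detect_bursts(np.arange(4) * 0.05, 60.0).n_bursts == 0

    def test_burst_rate_per_minute(self):
        burst = np.arange(5) * 0.05
        times = np.concatenate([burst, 30.0 + burst, 60.0 + burst])
        bs = detect_bursts(times, 120.0)
        assert bs.n_bursts == 3
        assert bs.burst_rate_per_min == pytest.approx(1.5)

    def test_matches_brute_force_on_random_trains(self, rng):
        for _ in range(200):
            isis = rng.choice([0.05, 0.1, 0.101, 0.15], size=rng.integers(1, 19))
            times = np.concatenate([[0.0], np.cumsum(isis)])
            expected = brute_force_bursts(times)
            bs = detect_bursts(times, 10.0)
            got = [
                (int(np.searchsorted(times, b.start_s)),
                 int(np.searchsorted(times, b.end_s)))
                for b in bs.bursts
            ]
            assert got == expected


class TestBurstIsiIqr:
    def test_constant_isis_zero_iqr(self):
        bs = detect_bursts(np.arange(10) * 0.05, 60.0)
        assert burst_isi_iqr(bs) == pytest.approx(0.0, abs=1e-9)

    def test_linear_interpolation_convention(self):
        times = np.concatenate([[0.0], np.cumsum([0.010, 0.020, 0.030, 0.040])])
        bs = detect_bursts(times, 60.0)
        assert burst_isi_iqr(bs) == pytest.approx(15.0)

    def test_scale_equivariance(self):
        isis = np.array([0.010, 0.025, 0.040, 0.015])
        t1 = np.concatenate([[0.0], np.cumsum(isis)])
        t2 = np.concatenate([[0.0], np.cumsum(2 * isis)])
        iqr1 = burst_isi_iqr(detect_bursts(t1, 60.0))
        iqr2 = burst_isi_iqr(detect_bursts(t2, 60.0))
        assert iqr2 == pytest.approx(2 * iqr1)

    def test_empty_burst_set_missing(self):
        assert np.isnan(burst_isi_iqr(detect_bursts(np.array([0.0, 1.0]), 60.0)))


class TestDrugTimecourse:
    def _baseline_trains(self, seed, n_units=50, rate=20.0, duration=300.0):
        gt = GroundTruth(unit_rates=[rate] * n_units, seed=seed)
        return generate_trains(gt, duration)

    def test_unmodulated_train_stays_near_one(self):
        trains = self._baseline_trains(seed=0)
        tc = drug_timecourse(trains, 60.0, bin_width_s=5.0, end_s=300.0)
        assert np.all(np.abs(tc.normalized_mfr - 1.0) < 0.2)
        assert tc.t10_s is None and tc.t50_s is None and tc.t90_s is None

    def test_baseline_bins_average_to_one(self):
        trains = self._baseline_trains(seed=1)
        tc = drug_timecourse(trains, 60.0, bin_width_s=5.0, end_s=300.0)
        baseline = tc.normalized_mfr[tc.bin_start_s < 0]
        assert baseline.mean() == pytest.approx(1.0)

    def test_instantaneous_silencing(self):
        trains = self._baseline_trains(seed=2)
        silenced = [t[t < 60.0] for t in trains]
        tc = drug_timecourse(silenced, 60.0, bin_width_s=5.0, end_s=120.0)
        first_mid = 2.5
        assert tc.t10_s == tc.t50_s == tc.t90_s == pytest.approx(first_mid)

    def test_exponential_decay_crossings(self):
        trains = self._baseline_trains(seed=3, n_units=100, duration=360.0)
        tau = 60.0
        mod, _ = apply_pharmacology(
            trains,
            [dict(label="ttx", kind="ttx", start=60.0, end=360.0, tau_s=tau)],
            seed=3,
        )
        tc = drug_timecourse(mod, 60.0, bin_width_s=5.0, end_s=360.0)
        assert tc.t50_s == pytest.approx(tau * np.log(2), abs=5.0)
        assert tc.t90_s == pytest.approx(tau * np.log(10), abs=5.0)
        assert tc.t10_s <= tc.t50_s <= tc.t90_s

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            drug_timecourse([np.array([100.0])], 60.0, end_s=120.0)


class TestPercentChange:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(76.0, 111.0, 46.0), (0.02, 1.9, 9400.0), (0.06, 1.2, 1900.0),
         (5.0, 5.0, 0.0)],
    )
    def test_reporting_convention(self, before, after, expected):
        assert percent_change(before, after) == expected

    def test_unrounded_value(self):
        assert percent_change(76.0, 111.0, digits=None) == pytest.approx(46.0526, abs=1e-3)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0)


class TestLfpPropagationSpeed:
    def test_two_point_arithmetic(self):
        positions = np.array([[0.0, 0.0], [600.0, 0.0]])
        speed = lfp_propagation_speed(
            None, positions, peak_times_s=np.array([0.0, 0.002])
        )
        assert speed == pytest.approx(300.0)

    def test_planted_wave_recovered_within_5_percent(self):
        geometry = ChipGeometry()
        electrodes = list(range(10))  # one row, 60 um apart
        traces, _ = synthesize_lfp_wave(geometry, electrodes, 311.0, seed=4)
        positions = np.array([electrode_position(geometry, e) for e in electrodes])
        speed = lfp_propagation_speed(
            traces, positions, sampling_rate_hz=geometry.sampling_rate_hz
        )
        assert speed == pytest.approx(311.0, rel=0.05)

    def test_simultaneous_peaks_flag_infinite_speed(self):
        positions = np.array([[0.0, 0.0], [60.0, 0.0], [120.0, 0.0]])
        speed = lfp_propagation_speed(
            None, positions, peak_times_s=np.array([0.1, 0.1, 0.1])
        )
        assert np.isinf(speed)

    def test_single_electrode_rejected(self):
        with pytest.raises(ValueError):
            lfp_propagation_speed(None, np.array([[0.0, 0.0]]),
                                  peak_times_s=np.array([0.1]))
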