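"""Ground-truthed generator: rates, variability, bursts, raw rendering,
pharmacology epochs and dF/F movies."""

import numpy as np
import pytest

from hdmea import synth
from hdmea.chip import ChipGeometry
from hdmea.metrics import detect_bursts
from hdmea.spikes import detect_threshold
from hdmea.synth import (
    BurstSpec,
    Connection,
    GroundTruth,
    apply_pharmacology,
    generate_trains,
    spike_template,
    synthesize_raw,
    synthesize_vsdi,
)


class TestGenerateTrains:
    def test_fixed_seed_is_bit_identical(self):
        gt = GroundTruth(
            unit_rates=[3.0, 8.0],
            burst_specs={0: BurstSpec(2.0)},
            connections=[Connection(0, 1, 0.4)],
            seed=9,
        )
        first = generate_trains(gt, 120.0)
        second = generate_trains(gt, 120.0)
        for a, b in zip(first, second):
            assert np.array_equal(a, b)

    def test_zero_rate_unit_is_silent(self):
        trains = generate_trains(GroundTruth(unit_rates=[0.0], seed=0), 50.0)
        assert trains[0].size == 0

    def test_rate_and_cv_of_poisson_unit(self):
        # shape 1 -> Poisson: count ~ 10k +- 3 sd, ISI CV ~ 1
        trains = generate_trains(
            GroundTruth(unit_rates=[10.0], unit_isi_shape=[1.0], seed=4), 1000.0
        )
        n = trains[0].size
        assert abs(n - 10_000) < 3 * np.sqrt(10_000)
        isi = np.diff(trains[0])
        assert isi.std() / isi.mean() == pytest.approx(1.0, abs=0.05)

    def test_sub_poisson_cv_from_gamma_shape(self):
        shape = 1.8  # CV = 1/sqrt(1.8) ~ 0.745, as for prefrontal units
        trains = generate_trains(
            GroundTruth(unit_rates=[10.0], unit_isi_shape=[shape], seed=5), 1000.0
        )
        isi = np.diff(trains[0])
        assert isi.std() / isi.mean() == pytest.approx(1 / np.sqrt(shape), abs=0.05)

    def test_rate_conservation_over_units(self):
        rates = [0.5, 2.0, 20.0]
        trains = generate_trains(GroundTruth(unit_rates=rates, seed=6), 200.0)
        for rate, t in zip(rates, trains):
            se = np.sqrt(rate * 200.0)
            assert abs(t.size - rate * 200.0) < 3 * se + 1

    def test_planted_bursts_recoverable_by_detector(self):
        gt = GroundTruth(
            unit_rates=[0.2],
            burst_specs={0: BurstSpec(rate_per_min=2.0, n_spikes=5, intra_isi_ms=50.0)},
            seed=11,
        )
        trains = generate_trains(gt, 300.0)
        burst_set = detect_bursts(trains[0], 300.0)
        assert burst_set.n_bursts >= 5  # ~2/min planted

    def test_connection_copies_spikes_at_lag(self):
        gt = GroundTruth(
            unit_rates=[5.0, 0.0],
            connections=[Connection(0, 1, prob=1.0, lag_ms=6.0, jitter_ms=0.5)],
            seed=12,
        )
        src, tgt = generate_trains(gt, 100.0)
        assert tgt.size == pytest.approx(src.size, abs=3)  # boundary clipping only
        lags = tgt[:, None] - src[None, :]
        nearest = np.abs(lags).min(axis=1)
        assert np.median(nearest) < 0.01


class TestSynthesizeRaw:
    def test_no_units_no_noise_gives_zero_traces(self, small_geometry):
        gt = GroundTruth(unit_rates=[0.0], seed=0)
        raw = synthesize_raw([np.empty(0)], small_geometry, gt, noise_sd_uv=0.0,
                             duration=0.1)
        assert np.all(raw.voltage_uv == 0)

    def test_single_spike_minimum_matches_template(self, small_geometry):
        gt = GroundTruth(unit_rates=[1.0], amplitudes_uv=[300.0], electrodes=[2],
                         seed=0)
        raw = synthesize_raw([np.array([0.05])], small_geometry, gt,
                             noise_sd_uv=0.0, duration=0.1)
        trace = raw.voltage_uv[2]
        assert trace.min() == pytest.approx(-synth.NEGATIVE_FRACTION * 300.0, rel=1e-3)
        t_min = np.argmin(trace) / small_geometry.sampling_rate_hz
        assert t_min == pytest.approx(0.05, abs=1e-4)

    def test_sidecar_matches_threshold_detection(self, small_geometry):
        gt = GroundTruth(unit_rates=[5.0], amplitudes_uv=[300.0], electrodes=[0],
                         seed=2)
        trains = generate_trains(gt, 20.0)
        raw = synthesize_raw(trains, small_geometry, gt, noise_sd_uv=10.0,
                             duration=20.0)
        times, _ = detect_threshold(raw.voltage_uv[0],
                                    small_geometry.sampling_rate_hz)
        truth = np.array([row[2] for row in raw.sidecar])
        assert times.size == truth.size
        assert np.all(np.abs(times - truth) < 0.5e-3)

    def test_bad_electrode_mapping_rejected(self, small_geometry):
        gt = GroundTruth(unit_rates=[1.0], electrodes=[99], seed=0)
        with pytest.raises(ValueError):
            synthesize_raw([np.array([0.01])], small_geometry, gt)


class TestPharmacology:
    def test_infinite_tau_leaves_train_unchanged(self):
        train = np.linspace(0.0, 99.0, 500)
        out, labels = apply_pharmacology(
            [train], [dict(label="ttx", kind="ttx", start=50.0, end=100.0,
                           tau_s=1e12)], seed=0
        )
        assert np.array_equal(out[0], train)
        assert labels == [("ttx", 50.0, 100.0)]

    def test_ttx_thinning_follows_exponential_survival(self):
        rng = np.random.default_rng(0)
        train = np.sort(rng.uniform(60.0, 360.0, 60_000))
        tau = 60.0
        out, _ = apply_pharmacology(
            [train], [dict(label="ttx", kind="ttx", start=60.0, end=360.0,
                           tau_s=tau)], seed=1
        )
        observed = ((out[0] >= 60) & (out[0] < 360)).sum()
        survival = np.exp(-(train - 60.0) / tau)
        assert observed == pytest.approx(survival.sum(), rel=0.1)

    def test_kcl_zero_multiplier_empties_epoch(self):
        train = np.linspace(0.0, 10.0, 100)
        out, _ = apply_pharmacology(
            [train], [dict(label="kcl", kind="kcl", start=5.0, end=10.0,
                           multiplier=0.0)], seed=0
        )
        in_epoch = (out[0] >= 5.0) & (out[0] < 10.0)
        assert not in_epoch.any()

    def test_kcl_step_up_raises_rate(self):
        rng = np.random.default_rng(1)
        train = np.sort(rng.uniform(0.0, 120.0, 600))  # 5 Hz
        out, _ = apply_pharmacology(
            [train],
            [dict(label="kcl", kind="kcl", start=60.0, end=120.0, multiplier=3.0)],
            base_rates=[5.0], seed=2,
        )
        after = ((out[0] >= 60) & (out[0] < 120)).sum()
        assert after == pytest.approx(3 * 5.0 * 60.0, rel=0.2)

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError):
            apply_pharmacology(
                [np.array([1.0])],
                [dict(label="a", kind="kcl", start=0.0, end=10.0, multiplier=1.0),
                 dict(label="b", kind="kcl", start=5.0, end=15.0, multiplier=1.0)],
            )


class TestSynthesizeVsdi:
    def test_zero_amplitude_matches_baseline_statistics(self):
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        stack = synthesize_vsdi((20, 20), 100, 50, mask, 0.0, n_trials=4, seed=3)
        pre = stack[:, :50]
        post = stack[:, 51:]
        assert abs(post.mean() - pre.mean()) < 0.01
        assert post.std() == pytest.approx(pre.std(), rel=0.02)

    def test_masked_pixels_receive_transient(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 2:5] = True
        stack = synthesize_vsdi((10, 10), 80, 40, mask, 10.0, n_trials=1, seed=4)
        onset = stack[0, 41]
        assert onset[mask].mean() > 5.0
        assert abs(onset[~mask].mean()) < 1.0

    def test_trials_share_mask_and_seed_reproduces(self):
        mask = np.zeros((8, 8), bool)
        mask[0, 0] = True
        a = synthesize_vsdi((8, 8), 60, 30, mask, 5.0, n_trials=3, seed=5)
        b = synthesize_vsdi((8, 8), 60, 30, mask, 5.0, n_trials=3, seed=5)
        assert np.array_equal(a, b)

    def test_bad_arguments_rejected(self):
        mask = np.zeros((4, 4), bool)
        with pytest.raises(ValueError):
            synthesize_vsdi((4, 4), 10, 5, mask, 1.0, n_trials=0)
        with pytest.raises(ValueError):
            synthesize_vsdi((4, 4), 10, 20, mask, 1.0)


def test_spike_template_negative_lobe_leads():
    template, i_min = spike_template(20_000.0, 300.0)
    assert template.min() == pytest.approx(-200.0, rel=1e-6)
    assert template.max() == pytest.approx(100.0, rel=1e-6)
    assert i_min < np.argmax(template)
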