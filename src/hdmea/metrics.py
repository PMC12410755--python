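"""Firing statistics, burst detection, drug-response time courses, percent
changes and LFP propagation speed.

Core conventions:

* CV = SD(ISI)/mean(ISI); CV2 is the pairwise local-variability statistic
  mean(2|ISI_{i+1} - ISI_i| / (ISI_{i+1} + ISI_i)), bounded in [0, 2].
* A burst is a maximal run of at least 5 consecutive spikes whose
  inter-spike intervals are all <= 100 ms (inclusive).
* Drug time courses (e.g. TTX wash-in) bin the population firing rate,
  normalise it to the 60 s of baseline before application, and report the
  times to 10/50/90% decrease, each requiring three consecutive
  sub-threshold bins to guard against noise.
* Quantiles use linear interpolation throughout, so the intra-burst ISI
  interquartile range is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal, stats

__all__ = [
    "UnitMetrics",
    "Burst",
    "BurstSet",
    "DrugTimeCourse",
    "unit_metrics",
    "detect_bursts",
    "burst_isi_iqr",
    "drug_timecourse",
    "percent_change",
    "lfp_propagation_speed",
]


@dataclass(frozen=True)
class UnitMetrics:
    mfr_hz: float
    cv: float  # nan when < 3 spikes
    cv2: float  # nan when < 3 spikes
    peak_to_peak_uv: float = float("nan")


def unit_metrics(
    spike_times: np.ndarray,
    epoch: Tuple[float, float],
    peak_to_peak_uv: float = float("nan"),
) -> UnitMetrics:
    """Mean firing rate, CV and CV2 of one unit inside an epoch."""
    start, end = epoch
    if end <= start:
        raise ValueError("epoch must have positive duration")
    t = np.asarray(spike_times, float)
    t = t[(t >= start) & (t < end)]
    mfr = t.size / (end - start)
    if t.size < 3:
        return UnitMetrics(mfr, float("nan"), float("nan"), peak_to_peak_uv)
    isi = np.diff(t)
    cv = float(isi.std(ddof=0) / isi.mean())
    pair = 2.0 * np.abs(np.diff(isi)) / (isi[1:] + isi[:-1])
    cv2 = float(pair.mean())
    return UnitMetrics(mfr, cv, cv2, peak_to_peak_uv)


@dataclass(frozen=True)
class Burst:
    start_s: float
    end_s: float
    n_spikes: int
    intra_isis_ms: np.ndarray


@dataclass
class BurstSet:
    """Bursts of one unit plus summary statistics over an epoch."""

    bursts: List[Burst]
    burst_rate_per_min: float
    spikes_per_burst: float  # nan when no bursts
    isi_iqr_ms: float  # nan when no bursts

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    def pooled_isis_ms(self) -> np.ndarray:
        if not self.bursts:
            return np.empty(0)
        return np.concatenate([b.intra_isis_ms for b in self.bursts])


def detect_bursts(
    spike_times: np.ndarray,
    epoch_duration_s: float,
    min_spikes: int = 5,
    max_isi_ms: float = 100.0,
) -> BurstSet:
    """Max-interval burst detection.

    A burst is a maximal run of consecutive spikes whose ISIs are all
    <= ``max_isi_ms`` (inclusive) containing at least ``min_spikes`` spikes.
    Bursts are non-overlapping by construction.
    """
    if epoch_duration_s <= 0:
        raise ValueError("epoch duration must be positive")
    t = np.sort(np.asarray(spike_times, float))
    bursts: List[Burst] = []
    if t.size >= min_spikes:
        # inclusive boundary, tolerant to float rounding of times at the edge
        max_isi_s = max_isi_ms * 1e-3
        short = np.diff(t) <= max_isi_s * (1 + 1e-9) + 1e-12
        # maximal runs of consecutive short ISIs
        i = 0
        while i < short.size:
            if not short[i]:
                i += 1
                continue
            j = i
            while j < short.size and short[j]:
                j += 1
            n_run = j - i + 1  # spikes i..j
            if n_run >= min_spikes:
                isis_ms = np.diff(t[i : j + 1]) * 1e3
                bursts.append(Burst(float(t[i]), float(t[j]), n_run, isis_ms))
            i = j
    rate = len(bursts) / (epoch_duration_s / 60.0)
    if bursts:
        spb = float(np.mean([b.n_spikes for b in bursts]))
        pooled = np.concatenate([b.intra_isis_ms for b in bursts])
        iqr = float(np.percentile(pooled, 75) - np.percentile(pooled, 25))
    else:
        spb = float("nan")
        iqr = float("nan")
    return BurstSet(bursts, rate, spb, iqr)


def burst_isi_iqr(burst_set: BurstSet) -> float:
    """Interquartile range (Q3 - Q1, linear-interpolation quantiles) of the
    pooled intra-burst ISIs, in ms; nan for an empty burst set."""
    pooled = burst_set.pooled_isis_ms()
    if pooled.size == 0:
        return float("nan")
    return float(np.percentile(pooled, 75) - np.percentile(pooled, 25))


@dataclass
class DrugTimeCourse:
    """Population MFR time course around a drug application, normalised to
    the 60 s baseline preceding it."""

    bin_width_s: float
    bin_start_s: np.ndarray  # relative to application time
    normalized_mfr: np.ndarray
    baseline_window_s: float
    t10_s: Optional[float]
    t50_s: Optional[float]
    t90_s: Optional[float]


def _time_to_decrease(
    mids: np.ndarray, norm: np.ndarray, fraction: float, n_consecutive: int
) -> Optional[float]:
    """First post-application bin midpoint where the normalised MFR drops to
    <= 1 - fraction and stays there for n_consecutive bins."""
    level = 1.0 - fraction
    post = mids > 0
    idx = np.flatnonzero(post)
    below = norm <= level
    for j, i in enumerate(idx):
        window = below[i : i + n_consecutive]
        if window.size == n_consecutive and window.all():
            return float(mids[i])
    return None


def drug_timecourse(
    trains: Sequence[np.ndarray],
    application_time_s: float,
    bin_width_s: float = 10.0,
    baseline_s: float = 60.0,
    end_s: Optional[float] = None,
    n_consecutive: int = 3,
) -> DrugTimeCourse:
    """Normalised population-MFR time course following a drug application.

    All trains are pooled per bin; bins are anchored at the application
    time and extend ``baseline_s`` (default 60 s) backwards.  The
    normalisation divides by the mean baseline bin rate, so baseline bins
    average to 1 by construction.  t10/t50/t90 are the first bin midpoints
    at which the normalised MFR has dropped by 10/50/90% and stays below
    for ``n_consecutive`` bins; None when the drop is never reached.
    """
    if baseline_s < 60.0 - 1e-9:
        raise ValueError("need at least 60 s of pre-application baseline")
    pooled = np.sort(np.concatenate([np.asarray(t, float) for t in trains]))
    if end_s is None:
        end_s = pooled[-1] if pooled.size else application_time_s
    t0 = application_time_s - baseline_s
    if pooled.size and pooled[0] < t0 - 1e-9:
        pooled = pooled[pooled >= t0]
    n_bins = int(np.ceil((end_s - t0) / bin_width_s))
    edges = t0 + bin_width_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(pooled, bins=edges)
    rates = counts / bin_width_s
    mids = (edges[:-1] + edges[1:]) / 2.0 - application_time_s
    baseline = rates[edges[1:] <= application_time_s + 1e-9]
    baseline_rate = baseline.mean() if baseline.size else 0.0
    if baseline_rate == 0:
        raise ZeroDivisionError("zero baseline firing rate; cannot normalise")
    norm = rates / baseline_rate
    return DrugTimeCourse(
        bin_width_s=bin_width_s,
        bin_start_s=edges[:-1] - application_time_s,
        normalized_mfr=norm,
        baseline_window_s=baseline_s,
        t10_s=_time_to_decrease(mids, norm, 0.10, n_consecutive),
        t50_s=_time_to_decrease(mids, norm, 0.50, n_consecutive),
        t90_s=_time_to_decrease(mids, norm, 0.90, n_consecutive),
    )


def percent_change(before: float, after: float, digits: Optional[int] = 0) -> float:
    """100 x (after - before) / before.

    Rounded to the nearest integer by default (the convention used when
    reporting condition comparisons, e.g. 76 -> 111 uV is +46%);
    ``digits=None`` returns the unrounded value.
    """
    if before == 0:
        raise ZeroDivisionError("percent change undefined for a zero baseline")
    change = 100.0 * (after - before) / before
    return change if digits is None else float(round(change, digits))


def lfp_propagation_speed(
    traces_uv: Optional[np.ndarray],
    positions_um: np.ndarray,
    sampling_rate_hz: Optional[float] = None,
    peak_times_s: Optional[np.ndarray] = None,
    lowpass_hz: float = 100.0,
) -> float:
    """Propagation speed of an LFP event across electrodes, in mm/s.

    Either raw ``traces_uv`` (one row per electrode; the LFP peak is the
    negative extremum after a 4th-order zero-phase Butterworth low-pass
    below ``lowpass_hz``) or precomputed ``peak_times_s`` may be given.
    The speed is the slope of the regression of inter-electrode distance
    (from the earliest electrode) on peak latency.  Identical latencies on
    all electrodes return ``inf`` (instantaneous within resolution).
    """
    positions = np.atleast_2d(np.asarray(positions_um, float))
    if peak_times_s is None:
        if traces_uv is None or sampling_rate_hz is None:
            raise ValueError("provide traces plus sampling rate, or peak times")
        traces = np.atleast_2d(np.asarray(traces_uv, float))
        sos = signal.butter(
            4, lowpass_hz, btype="lowpass", fs=sampling_rate_hz, output="sos"
        )
        filtered = signal.sosfiltfilt(sos, traces, axis=1)
        peak_times_s = np.argmin(filtered, axis=1) / sampling_rate_hz
    peak_times_s = np.asarray(peak_times_s, float)
    if peak_times_s.size < 2:
        raise ValueError("need LFP peaks on at least 2 electrodes")
    if positions.shape[0] != peak_times_s.size:
        raise ValueError("positions and peak times must align")
    origin = positions[np.argmin(peak_times_s)]
    dist_mm = np.hypot(*(positions - origin).T) * 1e-3
    latency = peak_times_s - peak_times_s.min()
    if np.allclose(latency, 0):
        return float("inf")
    slope, _, _, _, _ = stats.linregress(latency, dist_mm)
    return float(slope)
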