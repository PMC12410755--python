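"""Threshold spike detection and per-electrode spike sorting.

Detection is a hard negative threshold (default -100 uV) on high-pass
filtered traces: an event is registered where the trace crosses below the
threshold, timed at the local minimum within 1 ms of the crossing, with a
refractory period suppressing retriggering.  Snippets of -1/+2 ms around
the minimum feed the sorter.

Sorting is per electrode: snippets are projected onto their top principal
components (3 by default), k-means is fitted for k = 1..4 and the number of
clusters is chosen with the gap statistic (uniform-box reference sets and
the one-standard-error rule).  At most four units are sorted per electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "UnitTrain",
    "detect_threshold",
    "sort_electrode",
    "gap_statistic",
]

MAX_UNITS_PER_ELECTRODE = 4


@dataclass
class UnitTrain:
    """One sorted unit on one electrode."""

    electrode: int
    unit_id: int
    spike_times: np.ndarray  # seconds, strictly increasing
    waveforms: Optional[np.ndarray] = None  # (n_spikes, snippet_len) uV
    mean_waveform: Optional[np.ndarray] = None
    peak_to_peak_uv: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if not 0 <= self.unit_id < MAX_UNITS_PER_ELECTRODE:
            raise ValueError(
                f"unit_id must be below {MAX_UNITS_PER_ELECTRODE} (per-electrode cap)"
            )
        if self.mean_waveform is None and self.waveforms is not None and len(self.waveforms):
            self.mean_waveform = np.asarray(self.waveforms, float).mean(axis=0)
        if self.mean_waveform is not None:
            mw = np.asarray(self.mean_waveform, float)
            self.peak_to_peak_uv = float(mw.max() - mw.min())

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


def detect_threshold(
    trace_uv: np.ndarray,
    sampling_rate_hz: float,
    threshold_uv: float = -100.0,
    refractory_ms: float = 1.0,
    search_ms: float = 1.0,
    snippet_ms: Tuple[float, float] = (1.0, 2.0),
) -> Tuple[np.ndarray, np.ndarray]:
    """Hard-threshold spike detection on one channel.

    Returns (spike_times_s, snippets).  An event is a crossing of the trace
    below ``threshold_uv``; the spike time is the sample of the local
    minimum within ``search_ms`` after the crossing, and crossings within
    ``refractory_ms`` of an accepted spike are suppressed.  Snippets cover
    -snippet_ms[0]..+snippet_ms[1] around the minimum (edge-padded at the
    trace boundaries).
    """
    if threshold_uv >= 0:
        raise ValueError("threshold must be negative (detection on the negative lobe)")
    trace = np.asarray(trace_uv, float)
    fs = sampling_rate_hz
    below = trace < threshold_uv
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if below.size and below[0]:
        crossings = np.concatenate([[0], crossings])
    search = max(1, int(round(search_ms * 1e-3 * fs)))
    refractory = refractory_ms * 1e-3
    pre = int(round(snippet_ms[0] * 1e-3 * fs))
    post = int(round(snippet_ms[1] * 1e-3 * fs))
    times: List[float] = []
    minima: List[int] = []
    last = -np.inf
    for c in crossings:
        window = trace[c : c + search + 1]
        i_min = c + int(np.argmin(window))
        t = i_min / fs
        if t - last < refractory:
            continue
        times.append(t)
        minima.append(i_min)
        last = t
    snippets = np.empty((len(minima), pre + post), float)
    padded = np.pad(trace, (pre, post), mode="edge")
    for row, i_min in enumerate(minima):
        snippets[row] = padded[i_min : i_min + pre + post]
    return np.asarray(times), snippets


def _dispersion(features: np.ndarray, k: int, seed: int) -> Tuple[float, np.ndarray]:
    """Within-cluster sum of squared distances (k-means inertia)."""
    if k == 1:
        centre = features.mean(axis=0)
        return float(((features - centre) ** 2).sum()), np.zeros(len(features), int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(features)
    return float(km.inertia_), labels


def gap_statistic(
    features: np.ndarray,
    k_range: Sequence[int] = (1, 2, 3, 4),
    n_reference: int = 20,
    seed: int = 0,
) -> Tuple[int, np.ndarray, np.ndarray]:
    """Choose the number of clusters by the gap statistic.

    gap(k) = E*[log W_k] - log W_k, where W_k is the within-cluster
    dispersion and the expectation is over ``n_reference`` uniform draws on
    the bounding box of the features.  The chosen k is the smallest k with
    gap(k) >= gap(k+1) - s(k+1) (one-standard-error rule), where s carries
    the sqrt(1 + 1/B) simulation correction.

    Returns (k, gap_curve, s_curve).
    """
    features = np.atleast_2d(np.asarray(features, float))
    n = len(features)
    k_range = sorted(int(k) for k in k_range)
    if k_range[0] < 1 or k_range[-1] > max(n, 1):
        raise ValueError("k_range must lie within [1, n_samples]")
    if n_reference < 10:
        raise ValueError("need at least 10 reference draws")
    if n <= 1:
        return 1, np.zeros(len(k_range)), np.zeros(len(k_range))
    lo, hi = features.min(axis=0), features.max(axis=0)
    if np.allclose(lo, hi):  # degenerate (all-identical) features
        return 1, np.zeros(len(k_range)), np.zeros(len(k_range))
    rng = np.random.default_rng(seed)
    eps = np.finfo(float).tiny
    log_w = np.empty(len(k_range))
    gaps = np.empty(len(k_range))
    s_k = np.empty(len(k_range))
    for j, k in enumerate(k_range):
        w, _ = _dispersion(features, k, seed)
        log_w[j] = np.log(w + eps)
        ref_log_w = np.empty(n_reference)
        for b in range(n_reference):
            ref = rng.uniform(lo, hi, size=features.shape)
            w_ref, _ = _dispersion(ref, k, seed)
            ref_log_w[b] = np.log(w_ref + eps)
        gaps[j] = ref_log_w.mean() - log_w[j]
        s_k[j] = ref_log_w.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_reference)
    chosen = k_range[-1]
    for j in range(len(k_range) - 1):
        if gaps[j] >= gaps[j + 1] - s_k[j + 1]:
            chosen = k_range[j]
            break
    return chosen, gaps, s_k


def sort_electrode(
    snippets: np.ndarray,
    spike_times: np.ndarray,
    electrode: int,
    n_features: int = 3,
    max_k: int = MAX_UNITS_PER_ELECTRODE,
    n_reference: int = 20,
    seed: int = 0,
) -> List[UnitTrain]:
    """Sort the snippets of one electrode into at most ``max_k`` units.

    Snippets are projected onto the top ``n_features`` principal components;
    k-means is fitted for k = 1..max_k and k is chosen by the gap statistic.
    Fewer than 10 snippets are returned as a single unit without clustering,
    matching the behaviour on sparsely active electrodes.  Unit ids are
    ordered by decreasing spike count; the result is invariant (up to unit
    relabelling) to the order of the input snippets.
    """
    snippets = np.atleast_2d(np.asarray(snippets, float))
    spike_times = np.asarray(spike_times, float)
    if len(snippets) != len(spike_times):
        raise ValueError("snippets and spike_times must align")
    max_k = min(max_k, MAX_UNITS_PER_ELECTRODE)
    order = np.argsort(spike_times)
    snippets, spike_times = snippets[order], spike_times[order]
    if len(snippets) < 10:
        return [
            UnitTrain(
                electrode=electrode,
                unit_id=0,
                spike_times=spike_times,
                waveforms=snippets,
            )
        ]
    n_features = min(n_features, snippets.shape[1], len(snippets))
    features = PCA(n_components=n_features, random_state=seed).fit_transform(snippets)
    k_range = list(range(1, min(max_k, len(snippets)) + 1))
    k, _, _ = gap_statistic(features, k_range, n_reference=n_reference, seed=seed)
    _, labels = _dispersion(features, k, seed)
    # stable unit ids: largest cluster first, ties broken by first spike time
    sizes = [(-(labels == lab).sum(), spike_times[labels == lab][0], lab)
             for lab in np.unique(labels)]
    units = []
    for unit_id, (_, _, lab) in enumerate(sorted(sizes)):
        sel = labels == lab
        units.append(
            UnitTrain(
                electrode=electrode,
                unit_id=unit_id,
                spike_times=spike_times[sel],
                waveforms=snippets[sel],
            )
        )
    return units
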