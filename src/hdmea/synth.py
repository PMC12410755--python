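"""Ground-truthed synthetic recordings for the HD-MEA analysis pipeline.

Real HD-MEA recordings of slices, spheroids and organoids are acquired with
proprietary hardware; this module generates surrogate data with the
statistical structure the downstream analyses assume, together with a
ground-truth sidecar so that every stage (detection, sorting, burst and
drug-response metrics, connectivity) can be validated by round trip.

Units are gamma-renewal point processes (shape k sets the ISI coefficient of
variation to 1/sqrt(k); cortical units in slice show CV ~0.7-0.75, i.e.
slightly sub-Poisson).  Bursts are planted as runs of >= 5 spikes with short
intra-burst intervals, directed connections are realised by copying source
spikes into targets with a transfer probability and a jittered lag <= 30 ms,
and pharmacology epochs thin (TTX wash-in) or scale (KCl steps) the
instantaneous rate.  Raw traces render each spike as a biphasic template
(negative lobe leading, two thirds of the peak-to-peak amplitude) in white
noise at 20 kHz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chip import ChipGeometry, electrode_position

__all__ = [
    "BurstSpec",
    "Connection",
    "CouplingScenario",
    "GroundTruth",
    "standard_network",
    "generate_trains",
    "spike_template",
    "synthesize_raw",
    "apply_pharmacology",
    "synthesize_vsdi",
    "synthesize_lfp_wave",
]

#: Fraction of the peak-to-peak amplitude carried by the (leading) negative
#: lobe of the spike template; detection uses a negative hard threshold.
NEGATIVE_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class BurstSpec:
    """Planted bursting: ``rate_per_min`` burst onsets per minute, each a run
    of ``n_spikes`` spikes at ``intra_isi_ms`` intervals."""

    rate_per_min: float
    n_spikes: int = 5
    intra_isi_ms: float = 50.0


@dataclass(frozen=True)
class Connection:
    """Directed functional connection: each source spike is copied into the
    target train with probability ``prob`` at ``lag_ms +- jitter_ms``."""

    source: int
    target: int
    prob: float
    lag_ms: float = 6.0
    jitter_ms: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("transfer probability must lie in [0, 1]")
        if not 0.0 < self.lag_ms <= 30.0:
            raise ValueError("lag mean must lie in (0, 30] ms")


@dataclass(frozen=True)
class CouplingScenario:
    """Electrode-coupling differences between planar and microneedle chips.

    3D microneedles reach better-preserved inner layers, which shows up as
    larger spike amplitudes and a larger fraction of electrodes seeing a
    unit.  The default scales reproduce the planar-vs-3D contrasts measured
    in cerebellar slices (peak-to-peak 76 vs 111 uV, ~80% more active
    electrodes on the 3D chip).
    """

    kind: str = "planar"
    amplitude_scale: float = 1.0
    active_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("planar", "needle3d"):
            raise ValueError(f"unknown coupling scenario {self.kind!r}")


PLANAR_COUPLING = CouplingScenario("planar", amplitude_scale=1.0, active_fraction=0.5)
NEEDLE3D_COUPLING = CouplingScenario(
    "needle3d", amplitude_scale=111.0 / 76.0, active_fraction=0.9
)


@dataclass
class GroundTruth:
    """Full parameterisation of a synthetic recording.

    One entry per planted unit in ``unit_rates`` (Hz), ``unit_isi_shape``
    (gamma shape; CV = 1/sqrt(shape)), ``amplitudes_uv`` (peak-to-peak) and
    ``electrodes`` (electrode index the unit couples to).  ``burst_specs``
    maps unit index -> :class:`BurstSpec`.  Identical seed and parameters
    give bit-identical output.
    """

    unit_rates: Sequence[float]
    unit_isi_shape: Optional[Sequence[float]] = None
    burst_specs: Dict[int, BurstSpec] = field(default_factory=dict)
    connections: List[Connection] = field(default_factory=list)
    amplitudes_uv: Optional[Sequence[float]] = None
    electrodes: Optional[Sequence[int]] = None
    coupling: CouplingScenario = field(default_factory=CouplingScenario)
    seed: int = 0

    def __post_init__(self) -> None:
        rates = np.asarray(self.unit_rates, dtype=float)
        if np.any(rates < 0):
            raise ValueError("unit rates must be non-negative")
        n = len(rates)
        if self.unit_isi_shape is None:
            self.unit_isi_shape = np.ones(n)
        if self.amplitudes_uv is None:
            self.amplitudes_uv = np.full(n, 150.0)
        if np.any(np.asarray(self.amplitudes_uv, dtype=float) <= 0):
            raise ValueError("amplitudes must be positive")
        if self.electrodes is None:
            self.electrodes = np.arange(n)
        for conn in self.connections:
            if not (0 <= conn.source < n and 0 <= conn.target < n):
                raise ValueError("connection endpoints must index planted units")

    @property
    def n_units(self) -> int:
        return len(self.unit_rates)

    def scaled_amplitudes(self) -> np.ndarray:
        return np.asarray(self.amplitudes_uv, float) * self.coupling.amplitude_scale

    def to_json(self) -> str:
        payload = asdict(self)
        payload["unit_rates"] = list(map(float, self.unit_rates))
        payload["unit_isi_shape"] = list(map(float, self.unit_isi_shape))
        payload["amplitudes_uv"] = list(map(float, self.amplitudes_uv))
        payload["electrodes"] = list(map(int, self.electrodes))
        payload["burst_specs"] = {str(k): asdict(v) for k, v in self.burst_specs.items()}
        return json.dumps(payload)


def standard_network(
    n_units: int = 20,
    n_connections: int = 15,
    rate_hz: float = 5.0,
    prob: float = 0.5,
    lag_ms: float = 6.0,
    jitter_ms: float = 2.0,
    seed: int = 0,
) -> GroundTruth:
    """The standard planted network used to validate link calling.

    A convergent feed-forward motif: the first ``n_connections`` units are
    sources, each projecting to one of the remaining units (targets picked
    round-robin, several convergent inputs per target, as in mossy-fibre
    style convergence).  No unit is both a source and a target and no two
    sources are correlated, so the planted adjacency is exactly the set of
    pairwise correlations a cross-correlogram method should report;
    recurrent motifs (chains, loops) would add genuine indirect
    correlations that pairwise methods cannot tell from direct links.
    """
    if n_connections >= n_units:
        raise ValueError("need more units than connections for disjoint roles")
    targets = list(range(n_connections, n_units))
    connections = [
        Connection(src, targets[src % len(targets)], prob, lag_ms, jitter_ms)
        for src in range(n_connections)
    ]
    return GroundTruth(
        unit_rates=[rate_hz] * n_units,
        connections=connections,
        seed=seed,
    )


def _renewal_train(
    rng: np.random.Generator, rate: float, shape: float, duration: float
) -> np.ndarray:
    """Gamma-renewal spike train at ``rate`` Hz on [0, duration)."""
    if rate <= 0:
        return np.empty(0)
    scale = 1.0 / (shape * rate)
    # draw ISIs in blocks until the train covers the duration
    n_guess = max(16, int(rate * duration * 1.5) + 4 * int(np.sqrt(rate * duration) + 1))
    times: List[np.ndarray] = []
    total = 0.0
    while total < duration:
        isis = rng.gamma(shape, scale, size=n_guess)
        block = total + np.cumsum(isis)
        times.append(block)
        total = block[-1]
    spikes = np.concatenate(times)
    return spikes[spikes < duration]


def generate_trains(ground_truth: GroundTruth, duration: float) -> List[np.ndarray]:
    """Generate per-unit spike-time arrays (seconds, sorted) on [0, duration).

    Background activity is a gamma-renewal process per unit; planted bursts
    are inserted as additional spike runs; connections copy source spikes to
    targets with the stated probability and lag distribution.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(ground_truth.seed)
    shapes = np.asarray(ground_truth.unit_isi_shape, float)
    trains = [
        _renewal_train(rng, float(rate), float(shapes[i]), duration)
        for i, rate in enumerate(ground_truth.unit_rates)
    ]
    # planted bursts: Poisson onsets, regular intra-burst runs
    for unit, spec in ground_truth.burst_specs.items():
        n_bursts = rng.poisson(spec.rate_per_min * duration / 60.0)
        onsets = np.sort(rng.uniform(0, duration, size=n_bursts))
        run = np.arange(spec.n_spikes) * spec.intra_isi_ms * 1e-3
        extra = (onsets[:, None] + run[None, :]).ravel()
        trains[unit] = np.concatenate([trains[unit], extra[extra < duration]])
    # realised connections: copy source spikes with probability and lag
    for conn in ground_truth.connections:
        src = trains[conn.source]
        keep = rng.random(src.size) < conn.prob
        lags = rng.normal(conn.lag_ms, conn.jitter_ms, size=int(keep.sum())) * 1e-3
        copied = src[keep] + lags
        copied = copied[(copied >= 0) & (copied < duration)]
        trains[conn.target] = np.concatenate([trains[conn.target], copied])
    return [np.sort(t) for t in trains]


def spike_template(
    sampling_rate_hz: float, peak_to_peak_uv: float, width_ms: float = 1.0
) -> Tuple[np.ndarray, int]:
    """Biphasic extracellular spike template and the index of its minimum.

    Negative half-sine lobe (depth = 2/3 of peak-to-peak) followed by a
    positive half-sine lobe (height = 1/3), total width ``width_ms``.
    """
    n = max(4, int(round(width_ms * 1e-3 * sampling_rate_hz)))
    n_neg = n // 2
    n_pos = n - n_neg
    neg = -NEGATIVE_FRACTION * peak_to_peak_uv * np.sin(np.pi * np.arange(n_neg) / n_neg)
    pos = (1 - NEGATIVE_FRACTION) * peak_to_peak_uv * np.sin(
        np.pi * np.arange(n_pos) / n_pos
    )
    template = np.concatenate([neg, pos])
    return template, int(np.argmin(template))


@dataclass
class RawRecording:
    """Raw synthetic voltage with its ground-truth sidecar."""

    voltage_uv: np.ndarray  # (n_channels, n_samples)
    sampling_rate_hz: float
    sidecar: List[Tuple[int, int, float]]  # (unit, electrode, spike_time_s)
    ground_truth: GroundTruth


def synthesize_raw(
    trains: Sequence[np.ndarray],
    geometry: ChipGeometry,
    ground_truth: GroundTruth,
    noise_sd_uv: float = 10.0,
    duration: Optional[float] = None,
) -> RawRecording:
    """Render spike trains as raw extracellular voltage at the chip sampling
    rate, plus a (unit, electrode, spike_time_s) sidecar.

    Each spike becomes a biphasic template scaled to the unit's peak-to-peak
    amplitude on its electrode, in additive white Gaussian noise.  The
    sidecar stores the rendered spike times (sample of the template minimum).
    """
    if noise_sd_uv < 0:
        raise ValueError("noise_sd_uv must be non-negative")
    electrodes = np.asarray(ground_truth.electrodes, int)
    if np.any(electrodes < 0) or np.any(electrodes >= geometry.n_electrodes):
        raise ValueError("unit mapped to nonexistent electrode")
    fs = geometry.sampling_rate_hz
    if duration is None:
        duration = max((t[-1] for t in trains if t.size), default=0.0) + 5e-3
    n_samples = int(np.ceil(duration * fs)) + 1
    rng = np.random.default_rng(ground_truth.seed + 1)
    if noise_sd_uv > 0:
        voltage = rng.normal(0.0, noise_sd_uv, size=(geometry.n_electrodes, n_samples))
    else:
        voltage = np.zeros((geometry.n_electrodes, n_samples))
    amplitudes = ground_truth.scaled_amplitudes()
    sidecar: List[Tuple[int, int, float]] = []
    for unit, times in enumerate(trains):
        template, i_min = spike_template(fs, float(amplitudes[unit]))
        chan = int(electrodes[unit])
        for t in times:
            start = int(round(t * fs)) - i_min
            stop = start + template.size
            if start < 0 or stop > n_samples:
                continue
            voltage[chan, start:stop] += template
            sidecar.append((unit, chan, (start + i_min) / fs))
    sidecar.sort(key=lambda row: row[2])
    return RawRecording(
        voltage_uv=voltage.astype(np.float32),
        sampling_rate_hz=fs,
        sidecar=sidecar,
        ground_truth=ground_truth,
    )


def apply_pharmacology(
    trains: Sequence[np.ndarray],
    epochs: Sequence[dict],
    base_rates: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> Tuple[List[np.ndarray], List[Tuple[str, float, float]]]:
    """Modulate spike trains over labelled drug epochs.

    ``epochs`` is an ordered, non-overlapping list of dicts with keys
    ``label``, ``start``, ``end`` and either ``kind="ttx"`` with ``tau_s``
    (spikes at time t survive with probability exp(-(t-start)/tau), the
    wash-in of a sodium-channel blocker) or ``kind="kcl"`` with
    ``multiplier`` (stepwise scaling of the instantaneous rate; multipliers
    above 1 superimpose extra Poisson spikes at (m-1) x the unit's base
    rate and need ``base_rates``).

    Returns the modulated trains and a (label, start, end) epoch list.
    """
    prev_end = -np.inf
    for spec in epochs:
        if spec["start"] < prev_end:
            raise ValueError("epochs must be ordered and non-overlapping")
        prev_end = spec["end"]
        if spec.get("kind") == "ttx" and spec["tau_s"] <= 0:
            raise ValueError("TTX decay constant must be positive")
        if spec.get("kind") == "kcl" and spec["multiplier"] < 0:
            raise ValueError("KCl rate multiplier must be non-negative")
    rng = np.random.default_rng(seed)
    out: List[np.ndarray] = []
    for unit, times in enumerate(trains):
        times = np.asarray(times, float)
        for spec in epochs:
            start, end = spec["start"], spec["end"]
            inside = (times >= start) & (times < end)
            if spec.get("kind") == "ttx":
                tau = spec["tau_s"]
                survival = np.exp(-(times[inside] - start) / tau)
                keep = np.ones_like(times, bool)
                keep[inside] = rng.random(int(inside.sum())) < survival
                times = times[keep]
            elif spec.get("kind") == "kcl":
                m = spec["multiplier"]
                if m <= 1:
                    keep = np.ones_like(times, bool)
                    keep[inside] = rng.random(int(inside.sum())) < m
                    times = times[keep]
                else:
                    if base_rates is None:
                        raise ValueError(
                            "multiplier > 1 requires base_rates to add spikes"
                        )
                    extra_rate = (m - 1.0) * float(base_rates[unit])
                    n_extra = rng.poisson(extra_rate * (end - start))
                    extra = rng.uniform(start, end, size=n_extra)
                    times = np.sort(np.concatenate([times, extra]))
        out.append(np.sort(times))
    labels = [(spec["label"], float(spec["start"]), float(spec["end"])) for spec in epochs]
    return out, labels


def synthesize_vsdi(
    frame_shape: Tuple[int, int],
    n_frames: int,
    stimulus_frame: int,
    mask: np.ndarray,
    response_amplitude_sd: float,
    n_trials: int = 10,
    noise_sd: float = 1.0,
    response_duration_frames: int = 8,
    seed: int = 0,
) -> np.ndarray:
    """Trial stack of synthetic dF/F movies, shape (n_trials, n_frames, h, w).

    Baseline is per-pixel Gaussian noise of SD ``noise_sd``; pixels in
    ``mask`` (boolean, shape ``frame_shape``) receive a transient of
    ``response_amplitude_sd`` baseline SDs starting one frame after the
    stimulus and lasting ``response_duration_frames``.  Trials share the
    mask.  An empty mask yields a pure-noise control movie.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 <= stimulus_frame < n_frames:
        raise ValueError("stimulus_frame must fall inside the movie")
    mask = np.asarray(mask, bool)
    if mask.shape != tuple(frame_shape):
        raise ValueError("mask shape must match frame_shape")
    rng = np.random.default_rng(seed)
    stack = rng.normal(0.0, noise_sd, size=(n_trials, n_frames, *frame_shape))
    onset = stimulus_frame + 1
    offset = min(n_frames, onset + response_duration_frames)
    stack[:, onset:offset, mask] += response_amplitude_sd * noise_sd
    return stack


def synthesize_lfp_wave(
    geometry: ChipGeometry,
    electrode_indices: Sequence[int],
    speed_mm_s: float,
    origin_index: Optional[int] = None,
    amplitude_uv: float = 200.0,
    width_ms: float = 5.0,
    duration_s: float = 0.5,
    noise_sd_uv: float = 0.5,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Traveling LFP wave across a set of electrodes.

    A negative Gaussian deflection of the given amplitude and width sweeps
    the electrodes at ``speed_mm_s``, starting at ``origin_index`` (default:
    the first listed electrode).  Returns (traces, planted_peak_times_s)
    with traces shaped (n_electrodes, n_samples) at the chip sampling rate.
    """
    if speed_mm_s <= 0:
        raise ValueError("speed must be positive")
    electrode_indices = list(electrode_indices)
    if origin_index is None:
        origin_index = electrode_indices[0]
    fs = geometry.sampling_rate_hz
    n_samples = int(duration_s * fs)
    t = np.arange(n_samples) / fs
    x0, y0 = electrode_position(geometry, origin_index)
    rng = np.random.default_rng(seed)
    traces = rng.normal(0.0, noise_sd_uv, size=(len(electrode_indices), n_samples))
    t_start = duration_s / 4.0
    peak_times = np.empty(len(electrode_indices))
    for i, idx in enumerate(electrode_indices):
        x, y = electrode_position(geometry, idx)
        dist_mm = np.hypot(x - x0, y - y0) * 1e-3
        peak = t_start + dist_mm / speed_mm_s
        traces[i] -= amplitude_uv * np.exp(-0.5 * ((t - peak) / (width_ms * 1e-3)) ** 2)
        peak_times[i] = peak
    return traces.astype(np.float64), peak_times
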