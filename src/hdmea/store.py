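"""Recording container, epoch/region bookkeeping, high-pass preprocessing
and active-channel selection.

A :class:`Recording` holds raw multichannel voltage (uV) and/or per-channel
spike rasters, together with the chip geometry, labelled epochs (e.g.
baseline vs drug phases), named region masks (sets of electrode indices
overlaying anatomy, such as a cortical subregion) and stimulation blanking
windows (the amplifiers are blanked for 500 us after each stimulation
pulse; spikes falling inside blanked windows are excluded from counts).

The on-disk format is an HDF5 dialect of this package (groups /voltage,
/rasters, /geometry, /epochs, /masks, /blanking; voltage stored as 16-bit
integers with a scale factor); the vendor's native format is not read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import h5py
import numpy as np
from scipy import signal

from .chip import ChipGeometry

__all__ = [
    "Recording",
    "BLANKING_S",
    "SCHEMA_VERSION",
    "highpass",
    "select_active",
    "exclude_blanked",
    "read_container",
    "write_container",
]

SCHEMA_VERSION = "1"
#: Post-stimulus amplifier blanking window (500 us).
BLANKING_S = 500e-6

#: Per-preparation high-pass cutoffs used during acquisition/analysis.
HIGHPASS_PRESETS_HZ = {"cortico_hippocampal": 10.0, "cerebellum": 50.0, "pfc": 100.0}


@dataclass
class Recording:
    """One recording session: voltage and/or rasters plus bookkeeping."""

    sampling_rate_hz: float
    geometry: ChipGeometry
    voltage_uv: Optional[np.ndarray] = None  # (n_channels, n_samples)
    rasters: Optional[Dict[int, np.ndarray]] = None  # channel -> spike times (s)
    epochs: List[Tuple[str, float, float]] = field(default_factory=list)
    region_masks: Dict[str, np.ndarray] = field(default_factory=dict)
    blanked_windows: List[Tuple[float, float]] = field(default_factory=list)
    highpass_cutoff_hz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.voltage_uv is None and self.rasters is None:
            raise ValueError("a Recording needs voltage traces or spike rasters")
        prev_end = -np.inf
        for label, start, end in sorted(self.epochs, key=lambda e: e[1]):
            if start < prev_end:
                raise ValueError(f"epoch {label!r} overlaps its predecessor")
            if start < 0 or end <= start:
                raise ValueError(f"epoch {label!r} has an invalid time span")
            prev_end = end
        if self.voltage_uv is not None and self.epochs:
            dur = self.voltage_uv.shape[1] / self.sampling_rate_hz
            if max(e[2] for e in self.epochs) > dur + 1e-9:
                raise ValueError("epochs exceed the recorded duration")
        n = self.geometry.n_electrodes
        for name, mask in self.region_masks.items():
            mask = np.asarray(mask, int)
            if mask.size and (mask.min() < 0 or mask.max() >= n):
                raise ValueError(f"region mask {name!r} holds invalid electrode indices")
            self.region_masks[name] = mask

    @property
    def duration_s(self) -> float:
        if self.voltage_uv is not None:
            return self.voltage_uv.shape[1] / self.sampling_rate_hz
        last_spike = max((t[-1] for t in self.rasters.values() if len(t)), default=0.0)
        last_epoch = max((e[2] for e in self.epochs), default=0.0)
        return max(last_spike, last_epoch)


def highpass(recording: Recording, cutoff_hz: float) -> Recording:
    """Zero-phase 4th-order Butterworth high-pass, applied per channel.

    Cutoffs of 10, 50 and 100 Hz are the presets used for
    cortico-hippocampal, cerebellar and prefrontal-cortex slices; any
    positive cutoff below Nyquist is accepted.  Forward-backward filtering
    avoids latency bias in downstream propagation-speed estimates.
    """
    if recording.voltage_uv is None:
        raise ValueError("highpass requires voltage traces")
    nyquist = recording.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz")
    sos = signal.butter(
        4, cutoff_hz, btype="highpass", fs=recording.sampling_rate_hz, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, recording.voltage_uv, axis=1)
    return replace(recording, voltage_uv=filtered, highpass_cutoff_hz=float(cutoff_hz))


def exclude_blanked(
    times: np.ndarray, blanked_windows: Sequence[Tuple[float, float]]
) -> np.ndarray:
    """Drop spike times falling inside stimulation blanking windows."""
    times = np.asarray(times, float)
    keep = np.ones(times.size, bool)
    for start, dur in blanked_windows:
        keep &= ~((times >= start) & (times < start + dur))
    return times[keep]


def select_active(
    rasters: Dict[int, np.ndarray],
    rate_threshold_hz: float,
    epoch: Tuple[float, float],
    region: Optional[Sequence[int]] = None,
    blanked_windows: Sequence[Tuple[float, float]] = (),
) -> Tuple[Set[int], int]:
    """Channels/units whose mean firing rate is strictly above threshold.

    The rate is computed inside ``epoch`` (and, if given, only channels in
    ``region`` are considered); "higher than" is strict, so ties at the
    threshold are excluded.  Returns the retained set and its size.
    """
    if rate_threshold_hz < 0:
        raise ValueError("rate threshold must be non-negative")
    start, end = epoch
    if end <= start:
        raise ValueError("epoch must have positive duration")
    duration = end - start
    candidates = set(rasters) if region is None else set(region) & set(rasters)
    retained = set()
    for chan in candidates:
        times = exclude_blanked(np.asarray(rasters[chan], float), blanked_windows)
        n = int(((times >= start) & (times < end)).sum())
        if n / duration > rate_threshold_hz:
            retained.add(chan)
    return retained, len(retained)


def write_container(recording: Recording, path: str) -> None:
    """Write a Recording to the package's HDF5 container.

    Voltage is quantised to int16 with a stored scale factor (one
    quantisation step of round-trip error); rasters, geometry, epochs and
    masks round-trip losslessly.
    """
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["sampling_rate_hz"] = recording.sampling_rate_hz
        if recording.highpass_cutoff_hz is not None:
            f.attrs["highpass_cutoff_hz"] = recording.highpass_cutoff_hz
        f.create_dataset("geometry", data=recording.geometry.to_json())
        if recording.voltage_uv is not None:
            v = np.asarray(recording.voltage_uv, float)
            peak = float(np.max(np.abs(v))) if v.size else 0.0
            scale = peak / 32767.0 if peak > 0 else 1.0
            ds = f.create_dataset(
                "voltage", data=np.round(v / scale).astype(np.int16)
            )
            ds.attrs["scale_uv"] = scale
        if recording.rasters is not None:
            grp = f.create_group("rasters")
            channels, times = [], []
            for chan in sorted(recording.rasters):
                t = np.asarray(recording.rasters[chan], np.float64)
                channels.append(np.full(t.size, chan, np.int64))
                times.append(t)
            grp.create_dataset(
                "channel",
                data=np.concatenate(channels) if channels else np.empty(0, np.int64),
            )
            grp.create_dataset(
                "time_s",
                data=np.concatenate(times) if times else np.empty(0, np.float64),
            )
            grp.attrs["channels_present"] = sorted(recording.rasters)
        ep = f.create_group("epochs")
        ep.create_dataset(
            "label", data=[e[0].encode() for e in recording.epochs]
        )
        ep.create_dataset("start_s", data=[e[1] for e in recording.epochs])
        ep.create_dataset("end_s", data=[e[2] for e in recording.epochs])
        masks = f.create_group("masks")
        for name, idx in recording.region_masks.items():
            masks.create_dataset(name, data=np.asarray(idx, np.int64))
        bl = f.create_group("blanking")
        bl.create_dataset("start_s", data=[w[0] for w in recording.blanked_windows])
        bl.create_dataset("dur_s", data=[w[1] for w in recording.blanked_windows])


def read_container(path: str) -> Recording:
    """Read a Recording written by :func:`write_container`."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported container schema version {version!r} "
                f"(expected {SCHEMA_VERSION!r})"
            )
        geometry = ChipGeometry.from_json(f["geometry"][()].decode())
        voltage = None
        if "voltage" in f:
            ds = f["voltage"]
            voltage = ds[()].astype(np.float64) * ds.attrs["scale_uv"]
        rasters = None
        if "rasters" in f:
            grp = f["rasters"]
            channel = grp["channel"][()]
            time_s = grp["time_s"][()]
            rasters = {
                int(c): time_s[channel == c]
                for c in grp.attrs["channels_present"]
            }
        epochs = [
            (lab.decode(), float(s), float(e))
            for lab, s, e in zip(
                f["epochs/label"][()], f["epochs/start_s"][()], f["epochs/end_s"][()]
            )
        ]
        masks = {name: ds[()] for name, ds in f["masks"].items()}
        blanked = [
            (float(s), float(d))
            for s, d in zip(f["blanking/start_s"][()], f["blanking/dur_s"][()])
        ]
        return Recording(
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            geometry=geometry,
            voltage_uv=voltage,
            rasters=rasters,
            epochs=epochs,
            region_masks=masks,
            blanked_windows=blanked,
            highpass_cutoff_hz=(
                float(f.attrs["highpass_cutoff_hz"])
                if "highpass_cutoff_hz" in f.attrs
                else None
            ),
        )
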