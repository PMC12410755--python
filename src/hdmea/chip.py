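"""Geometric and electrical model of planar and 3D (microneedle) HD-MEA chips.

The chips modelled here carry 4096 bidirectional electrodes on a 64x64 grid
with 60 um pitch, sampled at 20 kHz.  Planar electrodes are 21 um platinum
squares; 3D electrodes are gold microneedles standing on pedestals whose
width, together with the microchannel width between pedestals, tiles the
pitch.  The pedestal footprint determines the area of the chip in direct
contact with the tissue (the microchannels stay open for perfusion), and the
on-chip amplifier quality is summarised by a per-electrode signal-to-noise
ratio measured with an injected reference sine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "ChipGeometry",
    "SnrReport",
    "GEOMETRY_PRESETS",
    "electrode_position",
    "position_to_index",
    "contact_area",
    "snr_characterize",
]


@dataclass(frozen=True)
class ChipGeometry:
    """Electrode-grid layout and electrode architecture of one chip.

    All lengths in micrometres.  ``electrode_kind`` is ``"planar"`` (flat
    square electrodes) or ``"needle3d"`` (microneedles on pedestals).  For 3D
    chips the pedestal width plus the microchannel width equals the pitch.
    """

    n_rows: int = 64
    n_cols: int = 64
    pitch_um: float = 60.0
    sampling_rate_hz: float = 20_000.0
    electrode_kind: str = "planar"
    planar_side_um: Optional[float] = 21.0
    pedestal_width_um: Optional[float] = None
    channel_width_um: Optional[float] = None
    needle_height_um: Optional[float] = None
    needle_width_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.electrode_kind not in ("planar", "needle3d"):
            raise ValueError(f"unknown electrode_kind {self.electrode_kind!r}")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        for name in (
            "pitch_um",
            "sampling_rate_hz",
            "planar_side_um",
            "pedestal_width_um",
            "channel_width_um",
            "needle_height_um",
            "needle_width_um",
        ):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def array_side_um(self) -> float:
        """Side of the full recording area (n_cols x pitch)."""
        return self.n_cols * self.pitch_um

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, payload: str) -> "ChipGeometry":
        return cls(**json.loads(payload))


#: Bundled chip variants.  ``needle3d-large`` (90/26 um needles) was used for
#: acute slices, ``needle3d-small`` (65/14 um) for spheroids and organoids;
#: smc/imc/lmc are the pedestal/microchannel variants used in the viability
#: comparison (small/intermediate/large microchannels).
GEOMETRY_PRESETS = {
    "planar": ChipGeometry(electrode_kind="planar", planar_side_um=21.0),
    "needle3d-large": ChipGeometry(
        electrode_kind="needle3d",
        planar_side_um=None,
        pedestal_width_um=30.0,
        channel_width_um=30.0,
        needle_height_um=90.0,
        needle_width_um=26.0,
    ),
    "needle3d-small": ChipGeometry(
        electrode_kind="needle3d",
        planar_side_um=None,
        pedestal_width_um=30.0,
        channel_width_um=30.0,
        needle_height_um=65.0,
        needle_width_um=14.0,
    ),
    "smc": ChipGeometry(
        electrode_kind="needle3d",
        planar_side_um=None,
        pedestal_width_um=44.0,
        channel_width_um=16.0,
        needle_height_um=90.0,
        needle_width_um=26.0,
    ),
    "imc": ChipGeometry(
        electrode_kind="needle3d",
        planar_side_um=None,
        pedestal_width_um=36.0,
        channel_width_um=24.0,
        needle_height_um=90.0,
        needle_width_um=26.0,
    ),
    "lmc": ChipGeometry(
        electrode_kind="needle3d",
        planar_side_um=None,
        pedestal_width_um=30.0,
        channel_width_um=30.0,
        needle_height_um=90.0,
        needle_width_um=26.0,
    ),
}


@dataclass(frozen=True)
class SnrReport:
    """Per-electrode SNR (signal power / noise power) and the chip-level
    summary, defined as the median over electrodes."""

    per_electrode_snr: np.ndarray
    chip_snr: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        snr = np.asarray(self.per_electrode_snr, dtype=float)
        if snr.ndim != 1:
            raise ValueError("per_electrode_snr must be one-dimensional")
        if np.any(snr < 0):
            raise ValueError("SNR values must be non-negative")
        object.__setattr__(self, "per_electrode_snr", snr)
        object.__setattr__(self, "chip_snr", float(np.median(snr)))


def electrode_position(geometry: ChipGeometry, index: int) -> Tuple[float, float]:
    """Planar (x, y) coordinate in micrometres of an electrode.

    Electrodes are numbered row-major starting at 0; electrode 0 sits at the
    origin and electrode (row, col) at (col * pitch, row * pitch).
    """
    index = int(index)
    if not 0 <= index < geometry.n_electrodes:
        raise IndexError(
            f"electrode index {index} out of range [0, {geometry.n_electrodes})"
        )
    row, col = divmod(index, geometry.n_cols)
    return (col * geometry.pitch_um, row * geometry.pitch_um)


def position_to_index(geometry: ChipGeometry, x_um: float, y_um: float) -> int:
    """Inverse of :func:`electrode_position` for on-grid coordinates."""
    col = int(round(x_um / geometry.pitch_um))
    row = int(round(y_um / geometry.pitch_um))
    if not (0 <= col < geometry.n_cols and 0 <= row < geometry.n_rows):
        raise IndexError(f"coordinate ({x_um}, {y_um}) um is off the grid")
    return row * geometry.n_cols + col


def contact_area(geometry: ChipGeometry, rounded: bool = False) -> float:
    """Tissue-contact area of the chip in mm^2.

    For a 3D chip the tissue rests on the pedestals only, so the contact
    area is ``n_electrodes * pedestal_width**2`` (the microchannels between
    pedestals stay open for perfusion).  For a planar chip the tissue
    adheres to the full array footprint ``(n_cols * pitch)**2``.

    With ``rounded=True`` the value is reported to 0.1 mm^2, the precision
    used when quoting chip variants (e.g. 7.9 mm^2 for 44 um pedestals).
    """
    if geometry.electrode_kind == "needle3d":
        if geometry.pedestal_width_um is None:
            raise ValueError("needle3d geometry requires pedestal_width_um")
        area_um2 = geometry.n_electrodes * geometry.pedestal_width_um**2
    else:
        area_um2 = geometry.array_side_um**2
    area_mm2 = area_um2 * 1e-6
    return round(area_mm2, 1) if rounded else area_mm2


def _power(segment: np.ndarray) -> np.ndarray:
    """Mean squared amplitude after per-electrode mean removal."""
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    centred = segment - segment.mean(axis=1, keepdims=True)
    return np.mean(centred**2, axis=1)


def snr_characterize(
    signal_segment: np.ndarray, noise_segment: np.ndarray
) -> SnrReport:
    """Amplifier SNR from a reference-signal segment and a noise segment.

    Both arguments are (n_electrodes, n_samples) voltage traces sharing the
    sampling rate; the reference is typically an injected sine (100 uV
    peak-to-peak at 1 kHz).  Power is the mean squared mean-removed
    amplitude; SNRe = Psignal / Pnoise per electrode and the chip SNR is the
    median of the per-electrode values.
    """
    p_signal = _power(signal_segment)
    p_noise = _power(noise_segment)
    if p_signal.shape != p_noise.shape:
        raise ValueError("signal and noise segments must cover the same electrodes")
    if np.any(p_noise == 0):
        raise ZeroDivisionError("noise segment has zero power on some electrode")
    return SnrReport(per_electrode_snr=p_signal / p_noise)
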