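"""The VSD recording container and its HDF5 reader/writer.

A recording is a trials x channels x time fluorescence array plus the
metadata every analysis stage needs: sampling rate, stimulus-onset index,
condition label and the kind of signal stored (raw counts, fractional
fluorescence dF/F0, trial-averaged filtered VSD(t), or its temporal
derivative).  Times are reported in ms relative to stimulus onset
(onset = 0 ms, pre-stimulus negative); indices are 0-based.

HDF5 layout (one file per condition)::

    /values          float64, trials x channels x time
    /background_f0   float64, per channel (raw recordings only)
    /geometry/pos    float64, C x 2 (mm)
    /geometry/area   int, C
    attrs: sampling_rate_hz, stimulus_onset_index, condition, signal_kind,
           pitch_mm

Floating-point values round-trip bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np

from .geometry import HexGeometry

__all__ = ["VSDRecording", "FormatError", "read_recording", "write_recording",
           "SIGNAL_KINDS"]

SIGNAL_KINDS = ("raw_fluorescence", "fractional", "filtered", "derivative")


class FormatError(ValueError):
    """Raised when a recording file does not follow the documented layout."""


@dataclass
class VSDRecording:
    """Trials x channels x time optical recording with acquisition metadata."""

    values: np.ndarray
    sampling_rate_hz: float
    stimulus_onset_index: int
    condition: str
    signal_kind: str = "raw_fluorescence"
    background_f0: np.ndarray | None = None
    geometry: HexGeometry | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be trials x channels x time")
        if not 0 <= self.stimulus_onset_index < self.values.shape[2]:
            raise ValueError("stimulus_onset_index outside the time axis")
        if self.signal_kind not in SIGNAL_KINDS:
            raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")
        if self.geometry is not None and (
            self.geometry.n_channels != self.values.shape[1]
        ):
            raise ValueError("channel axis does not match geometry channel count")
        if self.background_f0 is not None:
            self.background_f0 = np.asarray(self.background_f0, dtype=np.float64)
            if self.background_f0.shape != (self.values.shape[1],):
                raise ValueError("background_f0 must be per channel")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def n_times(self) -> int:
        return self.values.shape[2]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to stimulus onset."""
        return (np.arange(self.n_times) - self.stimulus_onset_index) * self.dt_ms

    def with_values(self, values, signal_kind=None) -> "VSDRecording":
        kw = {"values": values}
        if signal_kind is not None:
            kw["signal_kind"] = signal_kind
        return replace(self, **kw)


_REQUIRED_ATTRS = ("sampling_rate_hz", "stimulus_onset_index", "condition",
                   "signal_kind")


def write_recording(rec: VSDRecording, path) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=rec.values)
        if rec.background_f0 is not None:
            f.create_dataset("background_f0", data=rec.background_f0)
        if rec.geometry is not None:
            g = f.create_group("geometry")
            g.create_dataset("pos", data=rec.geometry.pos)
            g.create_dataset("area", data=rec.geometry.area)
            f.attrs["pitch_mm"] = rec.geometry.pitch_mm
        f.attrs["sampling_rate_hz"] = float(rec.sampling_rate_hz)
        f.attrs["stimulus_onset_index"] = int(rec.stimulus_onset_index)
        f.attrs["condition"] = str(rec.condition)
        f.attrs["signal_kind"] = str(rec.signal_kind)


def read_recording(path) -> VSDRecording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "values" not in f:
            raise FormatError(f"{path}: missing dataset /values")
        for attr in _REQUIRED_ATTRS:
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing required attribute {attr!r}")
        values = f["values"][()]
        f0 = f["background_f0"][()] if "background_f0" in f else None
        geometry = None
        if "geometry" in f:
            geometry = HexGeometry(
                pos=f["geometry/pos"][()],
                area=f["geometry/area"][()],
                pitch_mm=float(f.attrs.get("pitch_mm", np.nan)),
            )
        return VSDRecording(
            values=values,
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            stimulus_onset_index=int(f.attrs["stimulus_onset_index"]),
            condition=str(f.attrs["condition"]),
            signal_kind=str(f.attrs["signal_kind"]),
            background_f0=f0,
            geometry=geometry,
        )
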