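"""Recording container and file I/O.

A :class:`Recording` bundles the multichannel extracellular signals, the
sampling rate, the motor-pulse event channel and the electrode layout
(ids with x/y positions in cm).  On disk a recording is an HDF5 file with
datasets ``/signals`` (channels x samples) and ``/events`` plus a
``sampling_rate`` attribute; the layout travels as a CSV table
``electrode,x_cm,y_cm``.  A plain multi-column CSV reader (time column +
one column per electrode) is provided for exported data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "default_layout",
    "read_layout_csv",
    "read_recording_csv",
]


def default_layout() -> pd.DataFrame:
    """12-electrode layout: a 2-mm-pitch 4x4 grid with the corners removed,
    centred on the 8-mm culture disc so every electrode lies inside it."""
    coords = [-0.3, -0.1, 0.1, 0.3]  # cm
    rows = []
    eid = 1
    for y in reversed(coords):
        for x in coords:
            if abs(x) == 0.3 and abs(y) == 0.3:
                continue  # corner outside usable area
            rows.append((eid, x, y))
            eid += 1
    return pd.DataFrame(rows, columns=["electrode", "x_cm", "y_cm"])


@dataclass
class Recording:
    """Multichannel sampled recording plus event channel and layout."""

    signals: np.ndarray                # (channels, samples)
    sampling_rate: float               # Hz
    event_channel: np.ndarray | None = None
    layout: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals must be finite")
        if self.layout is not None and self.layout["electrode"].duplicated().any():
            raise ValueError("layout electrode ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def save(self, path) -> None:
        """Write signals/events to HDF5 and the layout next to it (.layout.csv)."""
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("signals", data=self.signals)
            if self.event_channel is not None:
                f.create_dataset("events", data=self.event_channel)
            f.attrs["sampling_rate"] = float(self.sampling_rate)
            for k, v in self.meta.items():
                if isinstance(v, (str, int, float, bool)):
                    f.attrs[f"meta_{k}"] = v
        if self.layout is not None:
            self.layout.to_csv(path.with_suffix(path.suffix + ".layout.csv"), index=False)

    @classmethod
    def load(cls, path, layout_path=None) -> "Recording":
        path = Path(path)
        with h5py.File(path, "r") as f:
            signals = f["signals"][()]
            events = f["events"][()] if "events" in f else None
            rate = float(f.attrs["sampling_rate"])
            meta = {
                k[len("meta_"):]: v for k, v in f.attrs.items() if k.startswith("meta_")
            }
        if layout_path is None:
            candidate = path.with_suffix(path.suffix + ".layout.csv")
            layout_path = candidate if candidate.exists() else None
        layout = read_layout_csv(layout_path) if layout_path else None
        return cls(signals=signals, sampling_rate=rate, event_channel=events,
                   layout=layout, meta=meta)


def read_layout_csv(path) -> pd.DataFrame:
    """Read an ``electrode,x_cm,y_cm`` table."""
    layout = pd.read_csv(path)
    missing = {"electrode", "x_cm", "y_cm"} - set(layout.columns)
    if missing:
        raise ValueError(f"layout file missing columns: {sorted(missing)}")
    return layout


def read_recording_csv(path, sampling_rate=None, layout=None) -> Recording:
    """Read a plain multi-column CSV: a time column followed by one column
    per electrode.  The sampling rate is inferred from the time column
    unless given explicitly."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if sampling_rate is None:
        dt = np.diff(t)
        if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("cannot infer sampling rate from non-uniform time column")
        sampling_rate = 1.0 / dt[0]
    signals = df.iloc[:, 1:].to_numpy(dtype=float).T
    return Recording(signals=signals, sampling_rate=sampling_rate, layout=layout,
                     meta={"source": str(path)})
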