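"""Core session containers and plain-text session-bundle I/O.

A *session* is one continuous recording epoch: head-position tracking, one
spike train per sorted unit, and a single-channel LFP trace. Bundles are
written as a directory of delimited text files plus a raw little-endian
float32 LFP file with a JSON sidecar header, so every artifact is inspectable
with standard tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "PositionTrack",
    "SpikeTrain",
    "Lfp",
    "Session",
    "write_session",
    "read_session",
]


@dataclass
class PositionTrack:
    """Timestamped head position samples in arena (cm) coordinates.

    Timestamps must be strictly increasing and uniformly spaced (tracker
    frames). Speed is derived on demand from positions smoothed with a short
    moving window, because raw tracker jitter inflates instantaneous speed.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have identical shapes")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        if self.t.size < 2:
            raise ValueError("need at least two samples to define dt")
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        """Session length in seconds (sample span plus one frame)."""
        if self.t.size == 0:
            return 0.0
        if self.t.size == 1:
            return 0.0
        return float(self.t[-1] - self.t[0] + self.dt)

    def speed(self, smooth_window: float = 0.5) -> np.ndarray:
        """Instantaneous speed (cm/s) from smoothed positions.

        Parameters
        ----------
        smooth_window
            Length (s) of the moving-average window applied to x and y
            before differentiation. 0 disables smoothing.
        """
        if self.t.size < 2:
            return np.zeros(self.t.size)
        x, y = self.x, self.y
        if smooth_window > 0:
            size = max(1, int(round(smooth_window / self.dt)))
            x = uniform_filter1d(x, size=size, mode="nearest")
            y = uniform_filter1d(y, size=size, mode="nearest")
        vx = np.gradient(x, self.t)
        vy = np.gradient(y, self.t)
        return np.hypot(vx, vy)


@dataclass
class SpikeTrain:
    """One sorted unit's spike timestamps (s) within a session."""

    unit_id: int
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size >= 2 and np.any(np.diff(self.times) < 0):
            raise ValueError("spike times must be sorted")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class Lfp:
    """Single-channel local field potential trace."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass
class Session:
    """A recording session: tracking, spike trains, LFP and metadata."""

    name: str
    track: PositionTrack
    spikes: Sequence[SpikeTrain] = field(default_factory=list)
    lfp: Lfp | None = None
    meta: dict = field(default_factory=dict)


def write_session(session: Session, out_dir: str | Path) -> Path:
    """Write a session bundle (delimited text + raw float32 LFP) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tr = session.track
    pos = np.column_stack([tr.t, tr.x, tr.y])
    np.savetxt(out / "positions.tsv", pos, delimiter="\t",
               header="t\tx\ty", comments="", fmt="%.6f")
    spikes_dir = out / "spikes"
    spikes_dir.mkdir(exist_ok=True)
    for st in session.spikes:
        np.savetxt(spikes_dir / f"unit_{st.unit_id:03d}.tsv", st.times,
                   delimiter="\t", header="t", comments="", fmt="%.6f")
    if session.lfp is not None:
        raw = session.lfp.samples.astype("<f4")
        (out / "lfp.bin").write_bytes(raw.tobytes())
        header = {
            "sample_rate": session.lfp.sample_rate,
            "dtype": "<f4",
            "n_samples": int(raw.size),
            "units": "arbitrary",
        }
        (out / "lfp.json").write_text(json.dumps(header, sort_keys=True, indent=1))
    (out / "meta.json").write_text(
        json.dumps({"name": session.name, **session.meta}, sort_keys=True,
                   indent=1, default=_jsonable))
    return out


def read_session(in_dir: str | Path) -> Session:
    """Read a session bundle written by :func:`write_session`."""
    src = Path(in_dir)
    pos = np.loadtxt(src / "positions.tsv", delimiter="\t", skiprows=1, ndmin=2)
    track = PositionTrack(pos[:, 0], pos[:, 1], pos[:, 2])
    spikes = []
    spikes_dir = src / "spikes"
    if spikes_dir.is_dir():
        for f in sorted(spikes_dir.glob("unit_*.tsv")):
            unit_id = int(f.stem.split("_")[1])
            times = np.loadtxt(f, delimiter="\t", skiprows=1, ndmin=1)
            spikes.append(SpikeTrain(unit_id, times))
    lfp = None
    if (src / "lfp.json").exists():
        header = json.loads((src / "lfp.json").read_text())
        raw = np.frombuffer((src / "lfp.bin").read_bytes(), dtype=header["dtype"])
        lfp = Lfp(raw.astype(float), header["sample_rate"])
    meta = json.loads((src / "meta.json").read_text())
    name = meta.pop("name", src.name)
    return Session(name=name, track=track, spikes=spikes, lfp=lfp, meta=meta)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
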