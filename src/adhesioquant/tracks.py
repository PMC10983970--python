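"""Trajectory containers shared by the migration and kinetics modules.

A :class:`Track` is an ordered sequence of (frame, time, x, y) samples for a
single object (a cell or an adhesion punctum).  Positions are physical, in
microns; frame indices are 0-based and times are ``frame * dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


@dataclass
class Track:
    track_id: int
    frames: np.ndarray          # int, strictly increasing
    t_s: np.ndarray             # seconds
    xy_um: np.ndarray           # (n, 2) positions in microns

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        if self.xy_um.ndim != 2 or self.xy_um.shape[1] != 2:
            raise ValueError("xy_um must be an (n, 2) array")
        n = len(self.frames)
        if len(self.t_s) != n or len(self.xy_um) != n:
            raise ValueError("frames, t_s and xy_um must have equal length")
        if n > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def net_displacement_um(self) -> np.ndarray:
        return self.xy_um[-1] - self.xy_um[0]

    def translated(self, offset_xy: np.ndarray) -> "Track":
        return Track(self.track_id, self.frames.copy(), self.t_s.copy(),
                     self.xy_um + np.asarray(offset_xy, dtype=float))


@dataclass
class TrackSet:
    tracks: list[Track]
    dt_s: float
    gradient_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        self.gradient_axis = np.asarray(self.gradient_axis, dtype=float)
        norm = np.hypot(*self.gradient_axis)
        if norm == 0:
            raise ValueError("gradient_axis must be non-zero")
        self.gradient_axis = self.gradient_axis / norm

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for f, t, (x, y) in zip(tr.frames, tr.t_s, tr.xy_um):
                rows.append((tr.track_id, int(f), float(t), float(x), float(y)))
        return pd.DataFrame(rows, columns=TRACK_COLUMNS)

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dt_s: float,
                   gradient_axis=(1.0, 0.0)) -> "TrackSet":
        tracks = []
        for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id"):
            tracks.append(Track(int(tid),
                                grp["frame"].to_numpy(),
                                grp["t_s"].to_numpy(),
                                grp[["x_um", "y_um"]].to_numpy()))
        return cls(tracks, dt_s, np.asarray(gradient_axis, dtype=float))

    @classmethod
    def load_csv(cls, path, dt_s: float, gradient_axis=(1.0, 0.0)) -> "TrackSet":
        return cls.from_frame(pd.read_csv(path), dt_s, gradient_axis)
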