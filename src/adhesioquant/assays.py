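"""Bulk adhesion assays: cell spreading, shear-flow detachment, polarity.

These are the simple whole-cell quantifications that accompany punctae-level
analysis: spreading area from a binary cell map, cumulative percent
detachment under stepwise flow-rate increases, and the rear-to-front actin
density ratio of a migrating cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .images import CellMask, PlaneImage
from .tracks import Track

__all__ = [
    "DetachmentSeries",
    "DetachmentResult",
    "PolarityAxis",
    "spreading_area",
    "percent_detached",
    "rear_front_ratio",
    "axis_from_track",
]


@dataclass
class DetachmentSeries:
    """Cell counts through a stepwise shear-flow detachment assay.

    ``counts[0]`` is the reference count after the initial gentle wash;
    ``counts[i]`` is the number of cells remaining after flow interval ``i``
    (one count per flow rate).
    """

    flow_rates_ul_min: list[float]
    counts: list[int]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.flow_rates_ul_min) + 1:
            raise ValueError("need one count before flow plus one per flow rate")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.counts[0] <= 0:
            raise ValueError("reference count N0 must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "flow_rate_ul_min": [0.0] + list(self.flow_rates_ul_min),
                "count": self.counts,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DetachmentSeries":
        df = df.sort_values("flow_rate_ul_min")
        rates = df["flow_rate_ul_min"].tolist()
        counts = df["count"].astype(int).tolist()
        if rates and rates[0] == 0.0:
            rates = rates[1:]
        else:
            raise ValueError("expected a flow_rate 0 row carrying the reference count")
        return cls(rates, counts)


@dataclass
class DetachmentResult:
    flow_rates_ul_min: list[float]
    percent_detached: list[float]
    clamped: bool = False


@dataclass
class PolarityAxis:
    """Unit migration-direction vector anchored at the cell centroid."""

    direction_xy: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.direction_xy, dtype=float)
        norm = float(np.hypot(*v))
        if norm == 0:
            raise ValueError("polarity axis undefined for zero displacement")
        self.direction_xy = v / norm


def axis_from_track(track: Track, i: int = 0, eps_um: float = 1e-9) -> PolarityAxis:
    """Instantaneous migration axis from the displacement after sample ``i``."""
    if len(track) < 2:
        raise ValueError("need at least two samples to define a direction")
    disp = track.xy_um[i + 1] - track.xy_um[i]
    if np.hypot(*disp) <= eps_um:
        raise ValueError("cell displacement below eps; polarity axis undefined")
    return PolarityAxis(disp)


def spreading_area(mask: CellMask, pixel_size_um: float) -> float:
    """Cell spreading area in um^2 (pixel count x pixel area)."""
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    n = mask.n_pixels
    if n == 0:
        raise ValueError("empty mask")
    return float(n) * pixel_size_um ** 2


def percent_detached(series: DetachmentSeries) -> DetachmentResult:
    """Cumulative percent of cells detached after each flow interval.

    ``pct_i = 100 * (N0 - N_i) / N0`` relative to the post-wash reference
    count.  Counts exceeding N0 (cells drifting into view) produce a warning
    and a clamped-to-zero percentage with the ``clamped`` flag set.
    """
    n0 = series.counts[0]
    pct: list[float] = []
    clamped = False
    for n_i in series.counts[1:]:
        p = 100.0 * (n0 - n_i) / n0
        if p < 0:
            warnings.warn(
                f"count {n_i} exceeds reference {n0}; percent clamped to 0",
                stacklevel=2,
            )
            p = 0.0
            clamped = True
        pct.append(p)
    return DetachmentResult(list(series.flow_rates_ul_min), pct, clamped)


def rear_front_ratio(
    image: PlaneImage,
    mask: CellMask,
    axis: PolarityAxis,
    mode: str = "half",
) -> float:
    """Ratio of mean in-mask intensity behind vs ahead of the cell centroid.

    With ``mode='half'`` the cell is split by the line through its mask
    centroid perpendicular to the migration axis; "front" is the half in the
    direction of motion.  Pixels exactly on the dividing line belong to
    neither half, so reversing the axis inverts the ratio exactly.  With
    ``mode='thirds'`` only the leading and trailing thirds of the cell's
    extent along the axis are compared and the middle third is excluded.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if mode not in ("half", "thirds"):
        raise ValueError("mode must be 'half' or 'thirds'")
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 0:
        raise ValueError("empty mask")
    c_row, c_col = rows.mean(), cols.mean()
    ax, ay = axis.direction_xy  # x along columns, y along rows
    s = (cols - c_col) * ax + (rows - c_row) * ay
    if mode == "half":
        front = s > 1e-12
        rear = s < -1e-12
    else:
        lo, hi = s.min(), s.max()
        third = (hi - lo) / 3.0
        front = s > hi - third
        rear = s < lo + third
    if not front.any() or not rear.any():
        raise ValueError("degenerate split: one half of the cell is empty")
    vals = image.pixels[rows, cols].astype(float)
    return float(vals[rear].mean() / vals[front].mean())
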