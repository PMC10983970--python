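"""Adhesion lifetime analysis from time-lapse stacks.

An adhesion punctum assembles (intensity rises), plateaus, and disassembles
(intensity decays).  The analysis extracts a per-punctum intensity trace,
filters it (no endpoint-touching tracks, a minimum duration of 8 frames at
the 750 ms acquisition interval, i.e. 6 s), baseline-subtracts the first
frame, applies a 5-frame running average, and fits

* the assembly phase with a logistic, ``I(t) = A / (1 + exp(-r (t - t0)))``;
* the disassembly phase with an exponential decay,
  ``I(t) = A_d * exp(-k (t - t_peak))``,

splitting at the smoothed trace's maximum.  The half-maximal times are
``t_half_asm = t0`` (logistic midpoint) and
``t_half_dis = t_peak + ln(2)/k``, and the adhesion lifetime is the span
between them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .detection import DetectionParams, detect_punctae
from .images import CellMask, ImageStack

__all__ = [
    "LifetimeParams",
    "IntensityTrace",
    "LifetimeFit",
    "PunctumTrack",
    "regional_maxima_3x3",
    "track_punctae",
    "extract_traces",
    "smooth_trace",
    "fit_lifetime",
    "analyze_stack",
]


@dataclass(frozen=True)
class LifetimeParams:
    """Filtering and smoothing settings for trace extraction and fitting.

    ``min_frames`` is a duration filter: a track must span at least this many
    frames (8 frames at 0.75 s per frame = 6 s, using the frame-count * dt
    duration convention).  Tracks present in the first or last frame are
    removed because their assembly or disassembly is censored.
    """

    min_frames: int = 8
    smooth_window: int = 5
    exclude_endpoint_tracks: bool = True
    frame_interval_s: float = 0.75

    def __post_init__(self) -> None:
        if self.min_frames < 2:
            raise ValueError("min_frames must be >= 2")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def min_duration_s(self) -> float:
        """Minimum track duration in seconds (frame count x frame interval)."""
        return self.min_frames * self.frame_interval_s


@dataclass
class IntensityTrace:
    """Per-punctum intensity time series (seconds, arbitrary counts)."""

    track_id: int
    t_s: np.ndarray
    values: np.ndarray
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.t_s) != len(self.values):
            raise ValueError("t_s and values must have equal length")
        if len(self.t_s) > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    def baseline_subtract(self) -> "IntensityTrace":
        return IntensityTrace(self.track_id, self.t_s.copy(),
                              self.values - self.values[0], True)


@dataclass
class LifetimeFit:
    """Fitted assembly/disassembly kinetics and the derived lifetime."""

    track_id: int
    a_asm: float = math.nan
    r: float = math.nan
    t0_s: float = math.nan
    sse_asm: float = math.nan
    converged_asm: bool = False
    a_dis: float = math.nan
    k_dis: float = math.nan
    t_peak_s: float = math.nan
    sse_dis: float = math.nan
    converged_dis: bool = False
    t_half_asm_s: float = math.nan
    t_half_dis_s: float = math.nan
    lifetime_s: float = math.nan

    @property
    def converged(self) -> bool:
        return self.converged_asm and self.converged_dis


def regional_maxima_3x3(stack: ImageStack) -> ImageStack:
    """Suppress smooth background with a 3x3 white top-hat, per frame.

    The transform is ``frame - grayscale_opening(frame, 3x3 square)``: flat or
    slowly varying regions map to ~0 while local bright features narrower than
    the 3x3 element are retained.  Adding a constant to a frame leaves the
    output unchanged.
    """
    out = np.empty_like(stack.frames)
    for i in range(len(stack)):
        frame = stack.frames[i]
        opened = ndimage.grey_opening(frame, size=(3, 3), mode="nearest")
        out[i] = frame - opened  # opening <= frame, so no underflow
    return ImageStack(out, stack.pixel_size_um, stack.frame_interval_s, stack.bit_max)


@dataclass
class PunctumTrack:
    """A punctum followed through consecutive frames, with its pixel sets."""

    track_id: int
    frames: list[int]
    pixels: list[tuple[np.ndarray, np.ndarray]]  # (rows, cols) per frame
    centroids_rc: list[tuple[float, float]]

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def is_contiguous(self) -> bool:
        return all(b - a == 1 for a, b in zip(self.frames, self.frames[1:]))


def track_punctae(
    stack: ImageStack,
    mask: CellMask | None = None,
    detection: DetectionParams | None = None,
    link_max_px: float = 5.0,
) -> list[PunctumTrack]:
    """Detect punctae per frame and link them into tracks.

    Linking is greedy nearest-neighbour between consecutive frames with a
    maximum centroid displacement of ``link_max_px``; a punctum with no
    acceptable successor terminates its track.  If no mask is given, the
    whole frame is used (appropriate for background-suppressed stacks).
    """
    detection = detection or DetectionParams()
    if mask is None:
        mask = CellMask(np.ones(stack.frames.shape[1:], dtype=bool))
    per_frame = [detect_punctae(stack.plane(i), mask, detection) for i in range(len(stack))]

    tracks: list[PunctumTrack] = []
    active: dict[int, PunctumTrack] = {}  # current-frame punctum list index -> track
    next_id = 0
    prev_punctae = []
    for f, pset in enumerate(per_frame):
        cur = list(pset)
        links: dict[int, int] = {}
        if prev_punctae and cur:
            cand = []
            for i, p in enumerate(prev_punctae):
                for j, q in enumerate(cur):
                    d = math.hypot(p.centroid_rc[0] - q.centroid_rc[0],
                                   p.centroid_rc[1] - q.centroid_rc[1])
                    if d <= link_max_px:
                        cand.append((d, i, j))
            cand.sort()
            used_i: set[int] = set()
            used_j: set[int] = set()
            for d, i, j in cand:
                if i in used_i or j in used_j:
                    continue
                used_i.add(i)
                used_j.add(j)
                links[j] = i
        new_active: dict[int, PunctumTrack] = {}
        for j, q in enumerate(cur):
            if j in links and links[j] in active:
                tr = active[links[j]]
            else:
                tr = PunctumTrack(next_id, [], [], [])
                next_id += 1
                tracks.append(tr)
            tr.frames.append(f)
            tr.pixels.append((q.rows, q.cols))
            tr.centroids_rc.append(q.centroid_rc)
            new_active[j] = tr
        active = new_active
        prev_punctae = cur
    return tracks


def extract_traces(
    stack: ImageStack,
    punctae_tracks: list[PunctumTrack],
    params: LifetimeParams | None = None,
) -> list[IntensityTrace]:
    """Build baseline-subtracted intensity traces from punctum tracks.

    Applies the track-quality filters: tracks touching the first or last
    frame of the stack are removed (their kinetics are censored); tracks
    shorter than ``min_frames`` are removed; tracks that skip frames or whose
    pixel sets ever overlap another track's are removed in lieu of manual
    curation.  The trace value per frame is the mean intensity over the
    punctum's pixels, and the first-frame value is subtracted throughout.
    """
    params = params or LifetimeParams()
    n_frames = len(stack)
    last = n_frames - 1

    # occupancy counts for overlap rejection
    occupancy = np.zeros(stack.frames.shape, dtype=np.int16)
    for tr in punctae_tracks:
        for f, (rows, cols) in zip(tr.frames, tr.pixels):
            occupancy[f, rows, cols] += 1

    traces: list[IntensityTrace] = []
    n_dropped = 0
    for tr in punctae_tracks:
        if params.exclude_endpoint_tracks and (0 in tr.frames or last in tr.frames):
            n_dropped += 1
            continue
        if len(tr) < params.min_frames or not tr.is_contiguous:
            n_dropped += 1
            continue
        if any(occupancy[f, rows, cols].max() > 1
               for f, (rows, cols) in zip(tr.frames, tr.pixels)):
            n_dropped += 1
            continue
        vals = np.array([
            float(stack.frames[f][rows, cols].mean())
            for f, (rows, cols) in zip(tr.frames, tr.pixels)
        ])
        t = np.asarray(tr.frames, dtype=float) * stack.frame_interval_s
        traces.append(IntensityTrace(tr.track_id, t, vals - vals[0], True))
    if not traces and punctae_tracks:
        warnings.warn(f"no punctum tracks survived filtering ({n_dropped} dropped)",
                      stacklevel=2)
    return traces


def smooth_trace(trace: IntensityTrace, window: int = 5) -> IntensityTrace:
    """Centered running average; the window truncates at the boundaries."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    sm = (
        pd.Series(trace.values)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return IntensityTrace(trace.track_id, trace.t_s.copy(), sm,
                          trace.baseline_subtracted)


def _logistic(t, a, r, t0):
    return a / (1.0 + np.exp(-r * (t - t0)))


def _init_logistic(t: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    a0 = float(v.max())
    half = 0.5 * a0
    above = np.nonzero(v >= half)[0]
    t0_0 = float(t[above[0]]) if above.size else float(t[len(t) // 2])
    i10 = np.nonzero(v >= 0.1 * a0)[0]
    i90 = np.nonzero(v >= 0.9 * a0)[0]
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    rise = float(t[i90[0]] - t[i10[0]]) if (i10.size and i90.size) else 0.0
    r0 = math.log(81.0) / rise if rise > 0 else 1.0 / dt
    return a0, r0, t0_0


def fit_lifetime(
    trace: IntensityTrace,
    params: LifetimeParams | None = None,
    lifetime_mode: str = "interval",
) -> LifetimeFit:
    """Fit assembly (logistic) and disassembly (exponential) kinetics.

    The trace is split at its maximum sample (``t_peak``); the peak sample is
    included in both branch fits to stabilise short branches.  A branch whose
    data degenerate (peak at the first/last sample, or a non-positive peak)
    is flagged not converged, and no lifetime is reported.

    ``lifetime_mode='interval'`` (default) defines the lifetime as
    ``t_half_dis - t_half_asm``; ``'sum'`` instead sums the rise half-time
    measured from the trace start, ``(t0 - t_start) + ln(2)/k``.
    """
    params = params or LifetimeParams()
    if lifetime_mode not in ("interval", "sum"):
        raise ValueError("lifetime_mode must be 'interval' or 'sum'")
    t = trace.t_s
    v = trace.values
    if len(t) < params.min_frames:
        raise ValueError("trace shorter than min_frames")
    fit = LifetimeFit(track_id=trace.track_id)
    peak = int(np.argmax(v))
    vmax = float(v[peak])
    if vmax <= 0:
        return fit
    fit.t_peak_s = float(t[peak])
    span = float(t[-1] - t[0])

    # assembly branch: samples up to and including the peak
    if peak > 0:
        ta, va = t[: peak + 1], v[: peak + 1]
        a0, r0, t0_0 = _init_logistic(ta, va)
        lo = [1e-12 * vmax, 1e-9, float(t[0]) - span - 1.0]
        hi = [10.0 * vmax, 1e9, float(t[-1]) + span + 1.0]
        x0 = [min(max(a0, lo[0]), hi[0]), min(max(r0, lo[1]), hi[1]),
              min(max(t0_0, lo[2]), hi[2])]
        try:
            res = optimize.least_squares(
                lambda p: _logistic(ta, *p) - va, x0,
                bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            a, r, t0 = res.x
            if res.success and np.all(np.isfinite(res.x)) and r > 0:
                fit.a_asm, fit.r, fit.t0_s = float(a), float(r), float(t0)
                fit.sse_asm = float(np.sum(res.fun ** 2))
                fit.t_half_asm_s = float(t0)
                fit.converged_asm = True
        except Exception:
            pass

    # disassembly branch.  The peak sample sits at the junction of the two
    # kinetic regimes, and after running-average smoothing the half-window of
    # samples on either side of the junction (and the truncated windows at
    # the trace end) mix the two regimes; those samples bias k and are
    # excluded whenever enough pure-decay samples remain.  Short branches
    # fall back to using everything from the peak on.
    if peak < len(t) - 1:
        # a smoothed sample is pure decay only when its whole window lies
        # past the junction, and the smoothed argmax can sit up to half a
        # window before the junction: pad by a full window width.
        half = params.smooth_window // 2
        start, end = peak + 1 + 2 * half, len(t) - half
        if end - start < 3:
            start = peak + 1 if len(t) - peak - 1 >= 3 else peak
            end = len(t)
        td, vd = t[start:end], v[start:end]
        pos = vd > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(td[pos], np.log(vd[pos]), 1)
            k0 = max(-float(slope), 1e-6)
            ad0 = float(math.exp(intercept + slope * td[0]))
        else:
            k0, ad0 = 1.0 / (t[1] - t[0]), vmax
        lo = [1e-12 * vmax, 1e-9]
        hi = [10.0 * vmax, 1e9]
        x0 = [min(max(ad0, lo[0]), hi[0]), min(max(k0, lo[1]), hi[1])]
        try:
            res = optimize.least_squares(
                lambda p: p[0] * np.exp(-p[1] * (td - td[0])) - vd, x0,
                bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
            ad, k = res.x
            if res.success and np.all(np.isfinite(res.x)) and k > 0:
                fit.a_dis, fit.k_dis = float(ad), float(k)
                fit.sse_dis = float(np.sum(res.fun ** 2))
                fit.t_half_dis_s = fit.t_peak_s + math.log(2.0) / float(k)
                fit.converged_dis = True
        except Exception:
            pass

    if fit.converged:
        if lifetime_mode == "interval":
            lifetime = fit.t_half_dis_s - fit.t_half_asm_s
        else:
            lifetime = (fit.t0_s - float(t[0])) + math.log(2.0) / fit.k_dis
        if lifetime >= 0:
            fit.lifetime_s = float(lifetime)
        else:
            fit.converged_asm = fit.converged_dis = False
    return fit


def analyze_stack(
    stack: ImageStack,
    mask: CellMask | None = None,
    detection: DetectionParams | None = None,
    params: LifetimeParams | None = None,
    link_max_px: float = 5.0,
    lifetime_mode: str = "interval",
) -> pd.DataFrame:
    """End-to-end lifetime analysis of a time-lapse stack.

    Runs background suppression, per-frame punctae detection, linking, trace
    extraction, smoothing and kinetic fitting; returns one row per fitted
    punctum track.
    """
    params = params or LifetimeParams(frame_interval_s=stack.frame_interval_s)
    clean = regional_maxima_3x3(stack)
    ptracks = track_punctae(clean, mask, detection, link_max_px)
    traces = extract_traces(clean, ptracks, params)
    rows = []
    for trace in traces:
        sm = smooth_trace(trace, params.smooth_window)
        fit = fit_lifetime(sm, params, lifetime_mode)
        rows.append(
            (fit.track_id, fit.a_asm, fit.r, fit.t0_s, fit.a_dis, fit.k_dis,
             fit.t_peak_s, fit.t_half_asm_s, fit.t_half_dis_s, fit.lifetime_s,
             fit.sse_asm, fit.sse_dis, fit.converged)
        )
    return pd.DataFrame(
        rows,
        columns=["track_id", "A_asm", "r", "t0_s", "A_dis", "k_dis", "t_peak_s",
                 "t_half_asm_s", "t_half_dis_s", "lifetime_s", "sse_asm",
                 "sse_dis", "converged"],
    )
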