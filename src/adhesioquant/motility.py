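"""Cell migration metrics: linking, speed, MSD, chemotaxis gating.

Speeds are reported in um/min regardless of the acquisition interval (5 s
frames for random migration, 15 s for chemotaxis).  The mean square
displacement (MSD) is time-averaged within each track over all overlapping
interval pairs, then averaged (unweighted) across tracks — the convention of
the standard spreadsheet MSD tool for cell trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .images import PlaneImage
from .tracks import Track, TrackSet

__all__ = [
    "LinkParams",
    "MSDCurve",
    "GateResult",
    "link_tracks",
    "track_speed",
    "msd",
    "chemotaxis_gate",
    "spider_coordinates",
    "gradient_profile",
]


@dataclass(frozen=True)
class LinkParams:
    """Frame-to-frame linking and gap-closing limits (simple LAP-style).

    Defaults follow the standard settings for amoeboid cell tracking:
    25 um linking max distance, 10 um gap-closing max distance, 5-frame
    maximum gap.
    """

    link_max_um: float = 25.0
    gap_max_um: float = 10.0
    gap_max_frames: int = 5
    min_track_frames: int = 2
    method: str = "greedy"   # 'greedy' | 'hungarian'

    def __post_init__(self) -> None:
        if min(self.link_max_um, self.gap_max_um) <= 0:
            raise ValueError("distance limits must be positive")
        if self.gap_max_frames < 1:
            raise ValueError("gap_max_frames must be >= 1")
        if self.min_track_frames < 1:
            raise ValueError("min_track_frames must be >= 1")
        if self.method not in ("greedy", "hungarian"):
            raise ValueError("method must be 'greedy' or 'hungarian'")


@dataclass
class MSDCurve:
    lags_s: np.ndarray
    msd_um2: np.ndarray
    n_intervals: np.ndarray  # total displacement pairs contributing per lag


@dataclass
class GateResult:
    """Directionality gate: fraction of tracks with net motion up-gradient."""

    fraction_toward: float
    threshold: float
    passed: bool
    net_along_axis_um: np.ndarray


def _greedy_assign(pts_a: np.ndarray, pts_b: np.ndarray, max_dist: float) -> list[tuple[int, int]]:
    """One-to-one greedy matching by ascending distance, capped at max_dist."""
    if len(pts_a) == 0 or len(pts_b) == 0:
        return []
    d = np.linalg.norm(pts_a[:, None, :] - pts_b[None, :, :], axis=2)
    cand = [(d[i, j], i, j) for i in range(len(pts_a)) for j in range(len(pts_b))
            if d[i, j] <= max_dist]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    out = []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        out.append((i, j))
    return out


def _hungarian_assign(pts_a: np.ndarray, pts_b: np.ndarray, max_dist: float) -> list[tuple[int, int]]:
    """Minimal-total-distance one-to-one matching, links beyond max_dist forbidden."""
    from scipy.optimize import linear_sum_assignment

    if len(pts_a) == 0 or len(pts_b) == 0:
        return []
    d = np.linalg.norm(pts_a[:, None, :] - pts_b[None, :, :], axis=2)
    big = max_dist * (len(pts_a) + len(pts_b) + 1)
    cost = np.where(d <= max_dist, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if d[i, j] <= max_dist]


def link_tracks(
    detections: list[np.ndarray],
    params: LinkParams | None = None,
    dt_s: float = 5.0,
    gradient_axis=(1.0, 0.0),
) -> TrackSet:
    """Link per-frame centroid lists into tracks.

    ``detections[f]`` is an (n_f, 2) array of (x, y) positions in um for
    frame ``f`` (empty frames allowed).  Consecutive frames are matched
    greedily by ascending distance with links beyond ``link_max_um``
    forbidden; afterwards, track ends are re-joined to later track starts
    within ``gap_max_frames`` and ``gap_max_um`` (gap closing).  Tracks with
    fewer than ``min_track_frames`` samples are discarded.
    """
    params = params or LinkParams()
    detections = [np.asarray(d, dtype=float).reshape(-1, 2) for d in detections]

    assign = _hungarian_assign if params.method == "hungarian" else _greedy_assign

    # stage 1: frame-to-frame linking
    segments: list[dict] = []     # {"frames": [...], "xy": [...]}
    active: dict[int, int] = {}   # detection index in prev frame -> segment idx
    prev = np.empty((0, 2))
    for f, pts in enumerate(detections):
        pairs = assign(prev, pts, params.link_max_um)
        linked_j = {j: i for i, j in pairs}
        new_active: dict[int, int] = {}
        for j in range(len(pts)):
            if j in linked_j and linked_j[j] in active:
                seg_idx = active[linked_j[j]]
            else:
                segments.append({"frames": [], "xy": []})
                seg_idx = len(segments) - 1
            segments[seg_idx]["frames"].append(f)
            segments[seg_idx]["xy"].append(pts[j])
            new_active[j] = seg_idx
        active = new_active
        prev = pts

    # stage 2: gap closing — join segment ends to later segment starts
    order = sorted(range(len(segments)), key=lambda i: segments[i]["frames"][0])
    merged_into: dict[int, int] = {}
    cand = []
    for i in range(len(segments)):
        for j in range(len(segments)):
            if i == j:
                continue
            end_f = segments[i]["frames"][-1]
            start_f = segments[j]["frames"][0]
            gap = start_f - end_f
            if not (1 <= gap <= params.gap_max_frames):
                continue
            dist = float(np.linalg.norm(
                np.asarray(segments[i]["xy"][-1]) - np.asarray(segments[j]["xy"][0])))
            if dist <= params.gap_max_um:
                cand.append((dist, i, j))
    cand.sort()
    closed_end: set[int] = set()
    closed_start: set[int] = set()
    joins: list[tuple[int, int]] = []
    for dist, i, j in cand:
        if i in closed_end or j in closed_start:
            continue
        closed_end.add(i)
        closed_start.add(j)
        joins.append((i, j))
    # resolve join chains
    successor = dict(joins)
    has_pred = {j for _, j in joins}
    tracks: list[Track] = []
    tid = 0
    for i in order:
        if i in has_pred:
            continue
        frames: list[int] = []
        xy: list[np.ndarray] = []
        k = i
        while True:
            frames.extend(segments[k]["frames"])
            xy.extend(segments[k]["xy"])
            if k in successor:
                k = successor[k]
            else:
                break
        if len(frames) < params.min_track_frames:
            continue
        fr = np.asarray(frames)
        tracks.append(Track(tid, fr, fr * dt_s, np.asarray(xy)))
        tid += 1
    return TrackSet(tracks, dt_s, np.asarray(gradient_axis, dtype=float))


def track_speed(track: Track) -> float:
    """Mean of per-step speeds, in um/min.

    The speed between consecutive samples is the Euclidean displacement over
    the elapsed time; the track speed is the unweighted average of those
    per-step speeds.  Steps across a closed gap contribute one displacement
    over the gapped interval.
    """
    if len(track) < 2:
        raise ValueError("track_speed requires at least two samples")
    disp = np.linalg.norm(np.diff(track.xy_um, axis=0), axis=1)
    dts = np.diff(track.t_s)
    return float(np.mean(disp / dts) * 60.0)


def msd(tracks: TrackSet, max_lag_fraction: float = 0.5) -> MSDCurve:
    """Ensemble MSD curve from time-averaged per-track MSDs.

    For a track with samples ``r_0..r_{m-1}`` at uniform spacing dt, the
    time-averaged MSD at lag ``n*dt`` is the mean of ``|r_{i+n} - r_i|^2``
    over all overlapping pairs.  Lags run up to ``max_lag_fraction`` of the
    track duration.  The ensemble curve averages per-track MSDs with equal
    weight at each lag.
    """
    if not (0 < max_lag_fraction <= 1):
        raise ValueError("max_lag_fraction must be in (0, 1]")
    per_lag_sum: dict[int, float] = {0: 0.0}
    per_lag_tracks: dict[int, int] = {0: 0}
    per_lag_pairs: dict[int, int] = {0: 0}
    for tr in tracks:
        m = len(tr)
        if m < 2:
            continue
        max_n = max(int(math.floor(max_lag_fraction * (m - 1))), 1)
        per_lag_tracks[0] += 1
        per_lag_pairs[0] += m
        for n in range(1, max_n + 1):
            d = tr.xy_um[n:] - tr.xy_um[:-n]
            sq = np.einsum("ij,ij->i", d, d)
            per_lag_sum[n] = per_lag_sum.get(n, 0.0) + float(sq.mean())
            per_lag_tracks[n] = per_lag_tracks.get(n, 0) + 1
            per_lag_pairs[n] = per_lag_pairs.get(n, 0) + len(sq)
    lags = sorted(per_lag_sum)
    msd_vals = np.array([per_lag_sum[n] / max(per_lag_tracks[n], 1) for n in lags])
    return MSDCurve(
        lags_s=np.asarray(lags, dtype=float) * tracks.dt_s,
        msd_um2=msd_vals,
        n_intervals=np.asarray([per_lag_pairs[n] for n in lags]),
    )


def chemotaxis_gate(tracks: TrackSet, threshold: float = 0.8) -> GateResult:
    """Fraction of tracks whose net displacement points up the gradient.

    A track counts "toward" the source iff the projection of its net
    displacement (last minus first position) onto the gradient axis is
    strictly positive; zero net projection counts against.  The dataset
    passes when the toward-fraction reaches ``threshold`` (0.8: at least 80%
    of cells moved toward the chemoattractant).
    """
    if len(tracks) == 0:
        raise ValueError("empty track set")
    axis = tracks.gradient_axis
    proj = np.array([float(np.dot(tr.net_displacement_um, axis)) for tr in tracks])
    frac = float(np.mean(proj > 0))
    return GateResult(frac, threshold, frac >= threshold, proj)


def spider_coordinates(tracks: TrackSet) -> TrackSet:
    """Translate every track so its first sample sits at the origin."""
    if len(tracks) == 0:
        raise ValueError("empty track set")
    shifted = [tr.translated(-tr.xy_um[0]) for tr in tracks]
    return TrackSet(shifted, tracks.dt_s, tracks.gradient_axis.copy())


def gradient_profile(image: PlaneImage, axis: str = "x"):
    """Line-scan validation of a chemoattractant gradient.

    Returns ``(profile, slope, increasing)`` where ``profile`` is the mean
    intensity per column (axis 'x') or per row (axis 'y'), ``slope`` the
    least-squares linear slope in counts per pixel, and ``increasing`` the
    sign of the trend.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    px = image.pixels.astype(float)
    profile = px.mean(axis=0) if axis == "x" else px.mean(axis=1)
    if np.ptp(profile) == 0:
        return profile, 0.0, False
    pos = np.arange(len(profile), dtype=float)
    slope, _ = np.polyfit(pos, profile, 1)
    return profile, float(slope), bool(slope > 0)
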