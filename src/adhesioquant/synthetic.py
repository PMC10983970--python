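"""Ground-truthed synthetic data mirroring the structure of the real assays.

Generators produce single cells (elliptical masks) containing
diffraction-limited punctae (sub-resolution Gaussian spots, areas of order
0.02-0.5 um^2 at 0.1 um/px) over noisy background; two-channel images with a
controlled fraction of co-localizing punctae; persistent-random-walk and
chemotactically biased cell tracks; adhesion intensity traces with a
logistic rise and exponential decay; and stepwise shear-flow detachment
counts.  Every generator takes an explicit seed and is bit-reproducible;
there is no global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .assays import DetachmentSeries
from .dynamics import IntensityTrace
from .images import CellMask, PlaneImage
from .tracks import Track, TrackSet

__all__ = [
    "SyntheticImageSpec",
    "PRWParams",
    "KineticTraceSpec",
    "DetachmentSimSpec",
    "SpotTruth",
    "GroundTruth",
    "gen_punctae_image",
    "gen_two_channel",
    "gen_tracks",
    "gen_intensity_trace",
    "gen_detachment_counts",
]


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for a single-cell punctae image.

    The cell is an ellipse (center, semi-axes in px, rotation in radians)
    containing ``n_punctae`` Gaussian spots of width ``spot_sigma_px`` and
    peak height ``spot_amplitude`` above a noisy background.  At the default
    0.1 um/px a spot thresholded near its half-maximum occupies a handful of
    pixels, landing in the 0.02-0.5 um^2 punctae size range.
    """

    shape_px: tuple[int, int] = (200, 200)
    pixel_size_um: float = 0.1
    cell_center_px: tuple[float, float] = (100.0, 100.0)   # (row, col)
    cell_semi_axes_px: tuple[float, float] = (70.0, 50.0)
    cell_rotation_rad: float = 0.0
    n_punctae: int = 5
    spot_sigma_px: float = 1.5
    spot_amplitude: float = 600.0
    background_mean: float = 200.0
    background_sd: float = 20.0
    cell_background_extra: float = 300.0   # in-cell cytoplasmic offset
    noise_model: str = "gaussian"
    min_separation_px: float = 12.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_punctae < 0:
            raise ValueError("n_punctae must be >= 0")
        if self.spot_amplitude <= 0:
            raise ValueError("spot_amplitude must be positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError("noise_model must be 'gaussian' or 'poisson'")
        if self.min_separation_px <= 2 * self.spot_sigma_px:
            raise ValueError("min_separation_px must exceed 2 * spot_sigma_px")

    @property
    def bit_max(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16


@dataclass(frozen=True)
class PRWParams:
    """Persistent-random-walk track generator settings.

    The heading evolves as an Ornstein-Uhlenbeck angle with correlation time
    ``persistence_time_s``; ``bias_strength`` replaces that fraction of each
    step with drift along +x (1 = straight chemotactic motion toward the
    source).  Defaults match the random-migration acquisition: 5 s frames
    for 5 min.
    """

    mean_speed_um_min: float = 6.0
    persistence_time_s: float = 60.0
    bias_strength: float = 0.0
    dt_s: float = 5.0
    n_frames: int = 61
    n_tracks: int = 30
    start_box_um: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_speed_um_min < 0:
            raise ValueError("mean_speed_um_min must be >= 0")
        if not (0 <= self.bias_strength <= 1):
            raise ValueError("bias_strength must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.persistence_time_s <= 0:
            raise ValueError("persistence_time_s must be positive")


@dataclass(frozen=True)
class KineticTraceSpec:
    """Adhesion intensity-trace generator: logistic rise, exponential decay.

    The noiseless value is ``A_asm / (1 + exp(-r (t - t0_s)))`` up to
    ``t_peak_s`` and the matched decay
    ``I(t_peak) * exp(-k_dis (t - t_peak_s))`` afterwards, sampled every
    750 ms by default.  Gaussian noise with SD ``noise_sd_frac * A_asm`` is
    added i.i.d.
    """

    A_asm: float = 100.0
    r: float = 1.0
    t0_s: float = 10.0
    k_dis: float = math.log(2) / 5.0
    t_peak_s: float = 20.0
    noise_sd_frac: float = 0.0
    dt_s: float = 0.75
    n_frames: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.k_dis <= 0:
            raise ValueError("rates r and k_dis must be positive")
        if self.t_peak_s < self.t0_s:
            raise ValueError("t_peak_s must be >= t0_s")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")

    def noiseless(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        rise = self.A_asm / (1.0 + np.exp(-self.r * (t - self.t0_s)))
        peak_val = self.A_asm / (1.0 + math.exp(-self.r * (self.t_peak_s - self.t0_s)))
        # exponent clamped at 0 where the rise branch applies anyway
        decay = peak_val * np.exp(-self.k_dis * np.maximum(t - self.t_peak_s, 0.0))
        return np.where(t <= self.t_peak_s, rise, decay)


@dataclass(frozen=True)
class DetachmentSimSpec:
    """Stepwise detachment: each flow interval removes cells binomially."""

    n0: int = 1000
    p_detach_per_step: tuple[float, ...] = (0.05, 0.08, 0.12, 0.18, 0.25)
    flow_rates_ul_min: tuple[float, ...] = (500, 750, 1000, 1250, 1500)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if any(not (0 <= p <= 1) for p in self.p_detach_per_step):
            raise ValueError("each detachment probability must lie in [0, 1]")
        if len(self.flow_rates_ul_min) != len(self.p_detach_per_step):
            raise ValueError("one flow rate per detachment step required")


@dataclass(frozen=True)
class SpotTruth:
    center_rc: tuple[float, float]
    sigma_px: float
    amplitude: float
    label: str = "spot"   # 'spot' | 'shared' | 'a_only' | 'b_only'


@dataclass
class GroundTruth:
    spots: list[SpotTruth] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.spots)

    def centers(self, label: str | None = None) -> np.ndarray:
        sel = [s.center_rc for s in self.spots if label is None or s.label == label]
        return np.asarray(sel, dtype=float).reshape(-1, 2)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(s) for s in self.spots], fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls([SpotTruth(center_rc=tuple(d["center_rc"]), sigma_px=d["sigma_px"],
                                  amplitude=d["amplitude"], label=d["label"])
                        for d in json.load(fh)])


def _ellipse_mask(spec: SyntheticImageSpec) -> np.ndarray:
    rr, cc = np.mgrid[0: spec.shape_px[0], 0: spec.shape_px[1]]
    return _ellipse_membership(spec, rr, cc)


def _ellipse_membership(spec, rr, cc):
    cr, ccol = spec.cell_center_px
    a, b = spec.cell_semi_axes_px
    th = spec.cell_rotation_rad
    dr, dc = rr - cr, cc - ccol
    u = dr * math.cos(th) + dc * math.sin(th)
    v = -dr * math.sin(th) + dc * math.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_spots(spec: SyntheticImageSpec, n: int, rng: np.random.Generator,
                 margin_frac: float = 0.85, max_tries: int = 500) -> np.ndarray:
    """Rejection-sample ``n`` spot centers inside the cell ellipse with the
    pairwise separation constraint; raise after bounded retries."""
    cr, ccol = spec.cell_center_px
    a, b = spec.cell_semi_axes_px
    th = spec.cell_rotation_rad
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        ok = False
        for _try in range(max_tries):
            # uniform in an inset ellipse so whole spots stay inside the cell
            t = rng.uniform(0, 2 * math.pi)
            rad = math.sqrt(rng.uniform(0, 1)) * margin_frac
            u, v = rad * a * math.cos(t), rad * b * math.sin(t)
            row = cr + u * math.cos(th) - v * math.sin(th)
            col = ccol + u * math.sin(th) + v * math.cos(th)
            if all(math.hypot(row - pr, col - pc) > spec.min_separation_px
                   for pr, pc in placed):
                placed.append((row, col))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place {n} spots at separation {spec.min_separation_px} px "
                f"inside the cell after {max_tries} tries"
            )
    return np.asarray(placed, dtype=float).reshape(-1, 2)


def _render(spec: SyntheticImageSpec, centers: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Expected image + noise, quantized to the requested bit depth."""
    shape = spec.shape_px
    cell = _ellipse_mask(spec)
    expect = np.full(shape, spec.background_mean, dtype=float)
    expect[cell] += spec.cell_background_extra
    win = int(math.ceil(5 * spec.spot_sigma_px))
    for row, col in centers:
        r0, r1 = max(int(row) - win, 0), min(int(row) + win + 1, shape[0])
        c0, c1 = max(int(col) - win, 0), min(int(col) + win + 1, shape[1])
        rr, cc = np.mgrid[r0:r1, c0:c1]
        g = np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * spec.spot_sigma_px ** 2))
        expect[r0:r1, c0:c1] += spec.spot_amplitude * g
    if spec.noise_model == "poisson":
        img = rng.poisson(expect).astype(float)
    else:
        img = expect + rng.normal(0.0, spec.background_sd, size=shape)
    img = np.clip(np.rint(img), 0, spec.bit_max)
    return img.astype(spec.dtype)


def gen_punctae_image(spec: SyntheticImageSpec) -> tuple[PlaneImage, CellMask, GroundTruth]:
    """Render one single-cell punctae image with its mask and ground truth."""
    rng = np.random.default_rng(spec.seed)
    centers = _place_spots(spec, spec.n_punctae, rng)
    img = _render(spec, centers, rng)
    truth = GroundTruth(
        [SpotTruth((float(r), float(c)), spec.spot_sigma_px, spec.spot_amplitude)
         for r, c in centers]
    )
    return (
        PlaneImage(img, spec.pixel_size_um, spec.bit_max),
        CellMask(_ellipse_mask(spec)),
        truth,
    )


def gen_two_channel(
    spec: SyntheticImageSpec,
    n_shared: int,
    n_a_only: int,
    n_b_only: int,
) -> tuple[PlaneImage, PlaneImage, CellMask, GroundTruth]:
    """Two-channel image pair with a controlled colocalization structure.

    Shared spots appear at identical centers in both channels; channel-
    exclusive spots are separated from every other spot by more than
    ``min_separation_px``.  The ground truth labels each spot shared /
    a_only / b_only.
    """
    if min(n_shared, n_a_only, n_b_only) < 0:
        raise ValueError("spot counts must be >= 0")
    rng = np.random.default_rng(spec.seed)
    total = n_shared + n_a_only + n_b_only
    centers = _place_spots(spec, total, rng)
    labels = (["shared"] * n_shared + ["a_only"] * n_a_only + ["b_only"] * n_b_only)
    in_a = np.array([lab in ("shared", "a_only") for lab in labels], dtype=bool)
    in_b = np.array([lab in ("shared", "b_only") for lab in labels], dtype=bool)
    img_a = _render(spec, centers[in_a], rng)
    img_b = _render(spec, centers[in_b], rng)
    truth = GroundTruth(
        [SpotTruth((float(r), float(c)), spec.spot_sigma_px, spec.spot_amplitude, lab)
         for (r, c), lab in zip(centers, labels)]
    )
    return (
        PlaneImage(img_a, spec.pixel_size_um, spec.bit_max),
        PlaneImage(img_b, spec.pixel_size_um, spec.bit_max),
        CellMask(_ellipse_mask(spec)),
        truth,
    )


def gen_tracks(p: PRWParams) -> TrackSet:
    """Sample persistent-random-walk (optionally +x biased) cell tracks.

    Step length is deterministic (``mean_speed * dt``) so the measured mean
    per-step speed of unbiased tracks equals ``mean_speed_um_min`` exactly up
    to float rounding; randomness enters through the heading process.
    """
    rng = np.random.default_rng(p.seed)
    step_um = p.mean_speed_um_min / 60.0 * p.dt_s
    if math.isinf(p.persistence_time_s):
        sigma_theta = 0.0
    else:
        sigma_theta = math.sqrt(2.0 * p.dt_s / p.persistence_time_s)
    tracks = []
    for tid in range(p.n_tracks):
        start = rng.uniform(0, p.start_box_um, size=2)
        theta = rng.uniform(0, 2 * math.pi)
        xy = np.empty((p.n_frames, 2))
        xy[0] = start
        for k in range(1, p.n_frames):
            theta += sigma_theta * rng.standard_normal() if sigma_theta else 0.0
            heading = np.array([math.cos(theta), math.sin(theta)])
            step = step_um * ((1.0 - p.bias_strength) * heading
                              + p.bias_strength * np.array([1.0, 0.0]))
            xy[k] = xy[k - 1] + step
        frames = np.arange(p.n_frames)
        tracks.append(Track(tid, frames, frames * p.dt_s, xy))
    return TrackSet(tracks, p.dt_s, np.array([1.0, 0.0]))


def gen_intensity_trace(spec: KineticTraceSpec) -> IntensityTrace:
    """Sample one adhesion intensity trace from the kinetic model."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_frames) * spec.dt_s
    values = spec.noiseless(t)
    if spec.noise_sd_frac > 0:
        values = values + rng.normal(0.0, spec.noise_sd_frac * spec.A_asm,
                                     size=spec.n_frames)
    return IntensityTrace(track_id=spec.seed, t_s=t, values=values,
                          baseline_subtracted=False)


def gen_detachment_counts(spec: DetachmentSimSpec) -> DetachmentSeries:
    """Binomial survival chain of adherent-cell counts under rising flow."""
    rng = np.random.default_rng(spec.seed)
    counts = [spec.n0]
    for p_step in spec.p_detach_per_step:
        counts.append(int(rng.binomial(counts[-1], 1.0 - p_step)))
    return DetachmentSeries(list(spec.flow_rates_ul_min), counts)
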