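"""End-to-end orchestration: stage chaining, configuration, manifests.

Conventions used throughout the pipeline outputs:

* image indices are 0-based (row, col); the physical position of a pixel is
  ``(index + 0.5) * pixel_size_um`` (pixel-center convention);
* frames are 0-based; times are ``frame * frame_interval_s`` seconds;
* CSV files are comma-separated UTF-8 with a header row and floats written
  with 6 significant digits, so identical runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detection import DetectionParams, colocalize, detect_punctae, segment_cell
from .images import CellMask, PlaneImage
from .motility import chemotaxis_gate, msd, spider_coordinates, track_speed
from .stats import RoutParams, group_summary, rout_outliers
from .synthetic import SyntheticImageSpec, gen_punctae_image
from .tracks import TrackSet

log = logging.getLogger("adhesioquant")
FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    command: str = "run"
    out_dir: str = "adhesioquant_out"
    pixel_size_um: float = 0.1
    frame_interval_s: float = 5.0
    seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)
    rout: RoutParams = field(default_factory=RoutParams)
    image_spec: SyntheticImageSpec | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        det = DetectionParams(**raw.pop("detection", {}))
        rout = RoutParams(**raw.pop("rout", {}))
        spec_raw = raw.pop("image_spec", None)
        if spec_raw is not None:
            for key in ("shape_px", "cell_center_px", "cell_semi_axes_px"):
                if key in spec_raw:
                    spec_raw[key] = tuple(spec_raw[key])
            spec = SyntheticImageSpec(**spec_raw)
        else:
            spec = None
        return cls(detection=det, rout=rout, image_spec=spec, **raw)


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def punctae_tables(pset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-punctum table and the one-row per-cell summary."""
    table = pset.to_frame()
    mean_area = float(table["area_um2"].mean()) if len(table) else float("nan")
    summary = pd.DataFrame(
        [{"n_punctae": len(pset), "mean_area_um2": mean_area}]
    )
    return table, summary


def detect_stage(image: PlaneImage, mask: CellMask | None,
                 params: DetectionParams, out_dir: Path) -> dict:
    pset = detect_punctae(image, mask, params)
    table, summary = punctae_tables(pset)
    write_csv(table, out_dir / "punctae.csv")
    write_csv(summary, out_dir / "punctae_summary.csv")
    log.info("detect: %d punctae", len(pset))
    return {"n_punctae": len(pset)}


def coloc_stage(img_a: PlaneImage, img_b: PlaneImage, mask: CellMask | None,
                params_a: DetectionParams, params_b: DetectionParams,
                out_dir: Path) -> dict:
    if mask is None:
        mask = segment_cell(img_a)
    set_a = detect_punctae(img_a, mask, params_a)
    set_b = detect_punctae(img_b, mask, params_b)
    counts = colocalize(set_a, set_b)
    df = pd.DataFrame([{
        "n_a_only": counts.n_a_only,
        "n_b_only": counts.n_b_only,
        "n_double": counts.n_double,
    }])
    write_csv(df, out_dir / "coloc.csv")
    log.info("coloc: %d double, %d A-only, %d B-only",
             counts.n_double, counts.n_a_only, counts.n_b_only)
    return df.iloc[0].to_dict()


def migrate_stage(tracks: TrackSet, out_dir: Path, mode: str = "random",
                  gate_threshold: float = 0.8) -> dict:
    speeds = pd.DataFrame(
        [(tr.track_id, track_speed(tr)) for tr in tracks if len(tr) >= 2],
        columns=["track_id", "speed_um_min"],
    )
    write_csv(speeds, out_dir / "speeds.csv")
    curve = msd(tracks)
    write_csv(
        pd.DataFrame({"lag_s": curve.lags_s, "msd_um2": curve.msd_um2,
                      "n": curve.n_intervals}),
        out_dir / "msd.csv",
    )
    record = {
        "n_tracks": len(tracks),
        "mean_speed_um_min": float(speeds["speed_um_min"].mean()),
    }
    if mode == "chemotaxis":
        gate = chemotaxis_gate(tracks, gate_threshold)
        spider = spider_coordinates(tracks)
        spider.save_csv(out_dir / "spider.csv")
        with open(out_dir / "gate.json", "w") as fh:
            json.dump({"fraction_toward": gate.fraction_toward,
                       "threshold": gate.threshold,
                       "passed": gate.passed}, fh, indent=1)
        record["gate_passed"] = gate.passed
        record["fraction_toward"] = gate.fraction_toward
    log.info("migrate: %d tracks, mean speed %.3g um/min",
             record["n_tracks"], record["mean_speed_um_min"])
    return record


def stats_stage(values: np.ndarray, params: RoutParams, out_dir: Path) -> dict:
    res = rout_outliers(values, params)
    write_csv(pd.DataFrame({"value": res.kept}), out_dir / "kept.csv")
    write_csv(pd.DataFrame({"value": res.flagged}), out_dir / "flagged.csv")
    summary = group_summary({"all": res.kept})
    write_csv(summary, out_dir / "summary.csv")
    log.info("stats: %d kept, %d flagged", len(res.kept), res.n_flagged)
    return {"n_kept": int(len(res.kept)), "n_flagged": int(res.n_flagged),
            "center": res.center, "rsdr": res.rsdr}


def run_pipeline(config: RunConfig) -> dict:
    """Run the simulate -> detect chain and write a manifest.

    Returns the manifest dict; all stage outputs land in ``config.out_dir``.
    Identical config + seed produce byte-identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = config.image_spec or SyntheticImageSpec(
        pixel_size_um=config.pixel_size_um, seed=config.seed)
    image, mask, truth = gen_punctae_image(spec)
    image.save(out_dir / "image.tif")
    mask.save(out_dir / "mask.tif")
    truth.to_json(out_dir / "truth.json")
    record = detect_stage(image, mask, config.detection, out_dir)
    manifest = {
        "software": f"adhesioquant {__version__}",
        "command": config.command,
        "seed": config.seed,
        "stages": {
            "simulate": {"n_spots_truth": len(truth)},
            "detect": record,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(name)s %(levelname)s: %(message)s",
    )
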