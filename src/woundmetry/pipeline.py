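"""End-to-end orchestration: preprocess, detect, crop, segment, post-process,
measure.

The pipeline consumes a directory of images plus a ``manifest.csv``
(filename, wound_id, day) — the format :func:`woundmetry.phantom.save_cohort`
writes — and produces per-image clean masks, a per-(wound, day) records
table, per-wound closure series, a cohort summary, and a run manifest with
the configuration and seed.  A failure on one image is logged and recorded
as a missing day for that wound; it never aborts the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .annotations import write_measurements_table
from .detect import crop_about_midpoint, oracle_detect, select_wound_of_interest
from .errors import ConfigurationError
from .measure import SplintGeometry, WoundRecord, average_series, build_series
from .postprocess import PostprocessConfig, clean_prediction
from .preprocess import downsample_half, normalize_orientation
from .segment import reference_segment
from .unet import UNetSegmenter, predict_maps

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    input_dir: str
    out_dir: str
    detector: str = "oracle"  # oracle | circle | external:<dir>
    segmenter: str = "reference"  # reference | model:<checkpoint>
    imputation: str = "nearest"  # none | mean | nearest
    crop_side: int = 352
    seed: int = 0
    halve_resolution: bool = True
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    geometry: SplintGeometry = field(default_factory=SplintGeometry)


class _LabelScene:
    """Adapter giving a label mask the scene interface oracle_detect expects."""

    def __init__(self, wound_mask: np.ndarray):
        self.wound_mask = wound_mask


def _load_label(path: Path) -> np.ndarray | None:
    if not path.exists():
        return None
    return np.asarray(Image.open(path))


def _transform_label(label: np.ndarray) -> np.ndarray:
    """Apply the preprocessing geometry (rotate + halve) to a label mask."""
    label = normalize_orientation(label)
    classes = [downsample_half((label == k).astype(np.float64)) >= 0.5 for k in (1, 2)]
    out = np.zeros(classes[0].shape, dtype=np.uint8)
    out[classes[1]] = 2
    out[classes[0]] = 1
    return out


def _build_detector(config: RunConfig, input_dir: Path):
    if config.detector == "oracle":

        def detect(image, stem, label):
            if label is None:
                raise ConfigurationError(f"{stem}: oracle detector needs a label mask")
            return oracle_detect(_LabelScene(label == 1))

    elif config.detector == "circle":
        from .detect import circle_detect

        def detect(image, stem, label):
            return circle_detect(image)

    elif config.detector.startswith("external:"):
        from .detect import read_detections

        det_dir = Path(config.detector.split(":", 1)[1])

        def detect(image, stem, label):
            return read_detections(det_dir / f"{stem}.txt")

    else:
        raise ConfigurationError(f"unknown detector {config.detector!r}")
    return detect


def _build_segmenter(config: RunConfig):
    if config.segmenter == "reference":
        return reference_segment
    if config.segmenter.startswith("model:"):
        model = UNetSegmenter.load(config.segmenter.split(":", 1)[1])
        return lambda crop: predict_maps(model, crop)
    raise ConfigurationError(f"unknown segmenter {config.segmenter!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all six stages; return paths of the written outputs."""
    input_dir = Path(config.input_dir)
    out_dir = Path(config.out_dir)
    manifest_path = input_dir / "manifest.csv"
    if not input_dir.is_dir() or not manifest_path.exists():
        raise ConfigurationError(
            f"input directory {input_dir} must exist and contain manifest.csv"
        )
    manifest = pd.read_csv(manifest_path)
    for col in ("filename", "wound_id", "day"):
        if col not in manifest.columns:
            raise ConfigurationError(f"manifest.csv lacks required column {col!r}")
    if manifest.empty:
        raise ConfigurationError("manifest.csv lists no images")

    detect = _build_detector(config, input_dir)
    segment = _build_segmenter(config)
    out_dir.mkdir(parents=True, exist_ok=True)
    masks_dir = out_dir / "masks"
    masks_dir.mkdir(exist_ok=True)

    records: list[WoundRecord] = []
    failures: list[dict] = []
    for row in manifest.itertuples():
        stem = Path(row.filename).stem
        try:
            image = np.asarray(Image.open(input_dir / row.filename).convert("RGB"))
            image = normalize_orientation(image)
            if config.halve_resolution:
                image = downsample_half(image)
            label = _load_label(input_dir / f"{stem}_label.png")
            if label is not None:
                label = _transform_label(np.asarray(label))

            woi = select_wound_of_interest(detect(image, stem, label))
            if woi is None:
                raise RuntimeError("no detection")
            crop, _prov = crop_about_midpoint(
                image, (woi.cx, woi.cy), side=config.crop_side
            )
            maps = segment(crop)
            clean = clean_prediction(maps, config.postprocess)
            out_label = np.zeros(clean.wound.shape, dtype=np.uint8)
            out_label[clean.splint] = 2
            out_label[clean.wound] = 1
            Image.fromarray(out_label).save(masks_dir / f"{stem}_clean.png")
            records.append(
                WoundRecord(
                    wound_id=str(row.wound_id),
                    day=int(row.day),
                    wound_px=float(clean.wound.sum()) if clean.wound_found else None,
                    splint_px=float(clean.splint.sum()) if clean.splint_found else None,
                )
            )
        except Exception as e:  # per-image failure isolation
            logger.warning("image %s failed: %s", row.filename, e)
            failures.append({"filename": row.filename, "error": str(e)})

    by_wound: dict[str, list[WoundRecord]] = {}
    for r in records:
        by_wound.setdefault(r.wound_id, []).append(r)
    n_days = int(manifest["day"].max()) + 1
    series = []
    for wid in sorted(by_wound):
        try:
            series.append(
                build_series(
                    sorted(by_wound[wid], key=lambda r: r.day),
                    imputation=config.imputation,
                    geometry=config.geometry,
                    day_grid=list(range(n_days)),
                )
            )
        except Exception as e:
            logger.warning("series %s failed: %s", wid, e)
            failures.append({"wound_id": wid, "error": str(e)})
    if not series:
        raise ConfigurationError("no wound series could be measured")

    series_path = out_dir / "series.csv"
    write_measurements_table(series, series_path)

    days, mean_curve, n = average_series(series)
    summary = pd.DataFrame(
        {
            "day": days,
            "mean_closure_pct": [f"{v:.2f}" for v in mean_curve],
            "n_wounds": n,
        }
    )
    summary_path = out_dir / "cohort_summary.csv"
    summary.to_csv(summary_path, index=False, lineterminator="\n")

    cfg = {
        "input_dir": str(config.input_dir),
        "out_dir": str(config.out_dir),
        "detector": config.detector,
        "segmenter": config.segmenter,
        "imputation": config.imputation,
        "crop_side": config.crop_side,
        "seed": config.seed,
        "halve_resolution": config.halve_resolution,
        "postprocess": asdict(config.postprocess),
        "geometry": asdict(config.geometry),
    }
    run_manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "version": __version__,
        "n_images": int(len(manifest)),
        "n_measured": len(records),
        "failures": failures,
    }
    manifest_out = out_dir / "run_manifest.json"
    manifest_out.write_text(json.dumps(run_manifest, indent=2) + "\n")
    return {
        "series_csv": series_path,
        "cohort_summary_csv": summary_path,
        "run_manifest": manifest_out,
        "series": series,
        "failures": failures,
    }
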