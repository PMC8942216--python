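"""Polygon annotations, label masks and measurement tables.

Annotation documents follow the LabelMe JSON dialect (``shapes[].label``,
``shapes[].points``, ``imageHeight``, ``imageWidth``).  Coordinates are
0-based with x = column and y = row, origin at the top-left *corner* of the
image, so the centre of pixel ``(r, c)`` is ``(x, y) = (c + 0.5, r + 0.5)``.
Polygon fill uses the pixel-centre even-odd rule: a pixel belongs to the
mask iff its centre lies inside the polygon.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure as skmeasure

from .errors import AnnotationError, InputError
from .measure import WoundSeries

__all__ = [
    "PolygonAnnotation",
    "KNOWN_LABELS",
    "polygons_to_mask",
    "mask_to_polygons",
    "read_annotation_document",
    "write_annotation_document",
    "write_measurements_table",
]

logger = logging.getLogger(__name__)

KNOWN_LABELS = ("wound", "splint")


@dataclass
class PolygonAnnotation:
    """A labelled polygon in pixel coordinates."""

    label: str
    points: np.ndarray  # (N, 2) of (x, y)
    image_size: tuple[int, int] | None = field(default=None)  # (H, W)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise AnnotationError(
                f"points must be an (N, 2) array, got shape {self.points.shape}"
            )
        if len(self.points) < 3:
            raise AnnotationError(
                f"a polygon needs at least 3 points, got {len(self.points)}"
            )
        if not np.isfinite(self.points).all():
            raise AnnotationError("polygon coordinates must be finite")


def _even_odd_fill(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize one polygon by the even-odd rule at pixel centres.

    Vectorized crossing-number test: a rightward ray from each pixel centre
    counts edges it crosses, using the half-open rule on edge endpoints so
    vertices are never double-counted.
    """
    H, W = shape
    px = np.arange(W) + 0.5
    py = np.arange(H) + 0.5
    PX = px[None, :]
    PY = py[:, None]
    inside = np.zeros(shape, dtype=bool)
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    for i in range(n):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % n]
        if y1 == y2:
            continue
        straddles = ((y1 <= PY) & (PY < y2)) | ((y2 <= PY) & (PY < y1))
        x_at = x1 + (PY - y1) * (x2 - x1) / (y2 - y1)
        inside ^= straddles & (PX < x_at)
    return inside


def polygons_to_mask(
    annotations: list[PolygonAnnotation], shape: tuple[int, int]
) -> dict[str, np.ndarray]:
    """Rasterize polygons into one binary mask per label.

    Multiple polygons sharing a label are unioned.  Labels absent from the
    input yield all-zero masks for every known label, so the result always
    has ``"wound"`` and ``"splint"`` keys.
    """
    masks = {label: np.zeros(shape, dtype=bool) for label in KNOWN_LABELS}
    for ann in annotations:
        masks.setdefault(ann.label, np.zeros(shape, dtype=bool))
        masks[ann.label] |= _even_odd_fill(ann.points, shape)
    return masks


def mask_to_polygons(
    mask: np.ndarray, label: str, min_points: int = 3
) -> list[PolygonAnnotation]:
    """Trace mask contours into polygons (sub-pixel marching squares).

    The inverse of :func:`polygons_to_mask` up to contour-tracing
    tolerance: re-rasterizing preserves the pixel count to within the
    boundary-pixel band (documented in the methods note).
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask.astype(np.float64), 1)
    out = []
    for contour in skmeasure.find_contours(padded, 0.5):
        # contour is (row, col) in padded coordinates; centre-of-pixel
        # convention adds 0.5 after removing the pad.
        pts = np.column_stack([contour[:, 1] - 0.5, contour[:, 0] - 0.5])
        if len(pts) >= min_points:
            out.append(PolygonAnnotation(label=label, points=pts, image_size=mask.shape))
    return out


def read_annotation_document(path) -> list[PolygonAnnotation]:
    """Read a LabelMe-style JSON document.

    Shapes with labels outside :data:`KNOWN_LABELS` are skipped with a
    logged warning (real annotation sets contain auxiliary shapes).
    Missing or malformed fields raise :class:`AnnotationError` naming the
    offending field.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise AnnotationError(f"{path}: not valid JSON: {e}") from e
    if "shapes" not in doc:
        raise AnnotationError(f"{path}: missing field 'shapes'")
    size = None
    if "imageHeight" in doc and "imageWidth" in doc:
        size = (int(doc["imageHeight"]), int(doc["imageWidth"]))
    out = []
    for i, shape in enumerate(doc["shapes"]):
        for key in ("label", "points"):
            if key not in shape:
                raise AnnotationError(f"{path}: shape {i} missing field '{key}'")
        label = shape["label"]
        if label not in KNOWN_LABELS:
            logger.warning("%s: skipping shape %d with unknown label %r", path, i, label)
            continue
        try:
            pts = np.asarray(shape["points"], dtype=np.float64)
        except (TypeError, ValueError) as e:
            raise AnnotationError(
                f"{path}: shape {i} field 'points' is malformed: {e}"
            ) from e
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise AnnotationError(f"{path}: shape {i} field 'points' is malformed")
        out.append(PolygonAnnotation(label=label, points=pts, image_size=size))
    return out


def write_annotation_document(
    annotations: list[PolygonAnnotation], path, image_path: str = ""
) -> None:
    """Write annotations as a LabelMe-style JSON document (lossless round trip)."""
    size = next((a.image_size for a in annotations if a.image_size), (0, 0))
    doc = {
        "version": "5.0.1",
        "flags": {},
        "imagePath": image_path,
        "imageHeight": int(size[0]),
        "imageWidth": int(size[1]),
        "shapes": [
            {
                "label": a.label,
                "points": [[float(x), float(y)] for x, y in a.points],
                "shape_type": "polygon",
                "group_id": None,
                "flags": {},
            }
            for a in annotations
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def write_measurements_table(series: list[WoundSeries], path) -> None:
    """Write one CSV row per (wound_id, day), sorted by wound then day.

    Areas are formatted to 4 decimals and closure percentages to 2, so
    re-exports of identical input are byte-identical.
    """
    if not series:
        raise InputError("no series to write")
    rows = []
    for s in sorted(series, key=lambda s: s.wound_id):
        for rec, closure in zip(s.records, s.closure_curve):
            rows.append(
                {
                    "wound_id": rec.wound_id,
                    "day": rec.day,
                    "wound_px": "" if rec.wound_px is None else f"{rec.wound_px:.0f}",
                    "splint_px": ""
                    if rec.splint_px is None
                    else f"{rec.splint_px:.4f}",
                    "area_mm2": f"{rec.area_mm2:.4f}",
                    "closure_pct": f"{closure:.2f}",
                    "splint_imputed": rec.splint_imputed,
                    "timepoint_filled": rec.timepoint_filled,
                }
            )
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
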