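"""Wound-of-interest localisation and fixed-size cropping.

Detection backends are pluggable: anything mapping an image to a list of
:class:`Detection` fits.  Two backends ship with the package — an oracle
that reads ground truth off a phantom scene (for tests and calibration
work) and a classical circular-edge detector that finds the splint ring by
Hough voting.  When several wounds are detected, the one with the highest
confidence is the wound of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color, feature, transform

from .errors import InputError

__all__ = [
    "Detection",
    "CropProvenance",
    "select_wound_of_interest",
    "crop_about_midpoint",
    "oracle_detect",
    "circle_detect",
    "read_detections",
    "write_detections",
]


@dataclass(frozen=True)
class Detection:
    """A detected object in scale-invariant (normalized) coordinates.

    ``cx``/``cy`` are the object midpoint as fractions of image width and
    height; ``w``/``h`` the normalized box extent; ``confidence`` in [0, 1].
    """

    cx: float
    cy: float
    w: float
    h: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise InputError(f"midpoint must be normalized, got ({self.cx}, {self.cy})")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise InputError(f"extent must be in (0, 1], got ({self.w}, {self.h})")
        if not 0.0 <= self.confidence <= 1.0:
            raise InputError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass(frozen=True)
class CropProvenance:
    """Mapping from crop pixel coordinates back to source-image coordinates.

    ``source[row0 + r - pad_top, col0 + c - pad_left]`` is crop pixel
    ``(r, c)`` wherever that index is in bounds; padded border pixels map
    outside the source.
    """

    row0: int
    col0: int
    pad_top: int
    pad_left: int
    side: int

    def to_source(self, r: int, c: int) -> tuple[int, int]:
        return self.row0 + r - self.pad_top, self.col0 + c - self.pad_left


def select_wound_of_interest(detections: list[Detection]) -> Detection | None:
    """The detection with maximal confidence; ties keep the first listed.

    Returns ``None`` for an empty list — a no-detection signal the caller
    records as a missing day, not an error.
    """
    if not detections:
        return None
    return max(detections, key=lambda d: d.confidence)


def crop_about_midpoint(
    image: np.ndarray,
    midpoint: tuple[float, float],
    side: int = 352,
) -> tuple[np.ndarray, CropProvenance]:
    """Extract an exactly ``side``×``side`` window centred on a normalized midpoint.

    The window is translated minimally to stay inside the image; a source
    dimension smaller than ``side`` is completed with symmetric zero
    padding.  Total function: any geometry yields a valid crop plus the
    provenance needed to map crop pixels back to source coordinates.
    """
    image = np.asarray(image)
    if image.ndim < 2 or image.shape[0] < 1 or image.shape[1] < 1 or side < 1:
        raise InputError("image must be at least 1x1 and side >= 1")
    H, W = image.shape[:2]
    cx, cy = midpoint
    cr, cc = int(round(cy * H)), int(round(cx * W))

    def window(dim: int, center: int) -> tuple[int, int]:
        if dim >= side:
            start = min(max(center - side // 2, 0), dim - side)
            return start, 0
        return 0, (side - dim) // 2

    row0, pad_top = window(H, cr)
    col0, pad_left = window(W, cc)
    rows = min(H, side)
    cols = min(W, side)
    crop_shape = (side, side) + image.shape[2:]
    crop = np.zeros(crop_shape, dtype=image.dtype)
    crop[pad_top : pad_top + rows, pad_left : pad_left + cols] = image[
        row0 : row0 + rows, col0 : col0 + cols
    ]
    return crop, CropProvenance(row0, col0, pad_top, pad_left, side)


def oracle_detect(scene) -> list[Detection]:
    """Ground-truth detections from a phantom scene.

    One detection per wound component; the component closest to the frame
    centre (the wound of interest by construction) gets confidence 1.0,
    satellites 0.5.  Empty wound mask yields an empty list.
    """
    mask = np.asarray(scene.wound_mask, dtype=bool)
    H, W = mask.shape
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return []
    idx = list(range(1, n + 1))
    centroids = ndimage.center_of_mass(mask, labels, idx)
    d2 = [
        (r - H / 2.0) ** 2 + (c - W / 2.0) ** 2 for r, c in centroids
    ]
    best = int(np.argmin(d2))
    dets = []
    for i, (r, c) in enumerate(centroids):
        sel = labels == idx[i]
        rows = np.flatnonzero(sel.any(axis=1))
        cols = np.flatnonzero(sel.any(axis=0))
        dets.append(
            Detection(
                cx=c / W,
                cy=r / H,
                w=max(cols[-1] - cols[0] + 1, 1) / W,
                h=max(rows[-1] - rows[0] + 1, 1) / H,
                confidence=1.0 if i == best else 0.5,
            )
        )
    return dets


def circle_detect(
    image: np.ndarray,
    radius_range: tuple[float, float] = (0.12, 0.45),
    vote_threshold: float = 0.3,
    max_detections: int = 4,
) -> list[Detection]:
    """Classical fallback detector: find splint rings by circular edge voting.

    Canny edges feed a Hough circle transform over radii given as fractions
    of the smaller image dimension; accumulator peaks above
    ``vote_threshold`` become detections whose confidence is the normalized
    vote strength.  Returns an empty list when nothing circular stands out.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        gray = color.rgb2gray(img)
    else:
        gray = img.astype(np.float64) / 255.0
    H, W = gray.shape
    m = min(H, W)
    r_lo = max(int(radius_range[0] * m), 4)
    r_hi = max(int(radius_range[1] * m), r_lo + 1)
    if np.ptp(gray) < 1e-6:
        return []
    # Quantile thresholds adapt to the image's own contrast range.
    edges = feature.canny(
        gray, sigma=2.0, use_quantiles=True, low_threshold=0.90, high_threshold=0.99
    )
    if not edges.any():
        return []
    # ~2 px radius resolution keeps the accumulator peak sharp.
    n_radii = min(max((r_hi - r_lo) // 2, 4), 40)
    radii = np.unique(np.linspace(r_lo, r_hi, n_radii).astype(int))
    hough = transform.hough_circle(edges, radii)
    accums, cxs, cys, rads = transform.hough_circle_peaks(
        hough,
        radii,
        total_num_peaks=max_detections,
        min_xdistance=r_lo,
        min_ydistance=r_lo,
        threshold=vote_threshold,
    )
    dets = []
    for a, x, y, r in zip(accums, cxs, cys, rads):
        if a < vote_threshold:
            continue
        dets.append(
            Detection(
                cx=float(np.clip(x / W, 0, 1)),
                cy=float(np.clip(y / H, 0, 1)),
                w=float(np.clip(2 * r / W, 1e-6, 1)),
                h=float(np.clip(2 * r / H, 1e-6, 1)),
                confidence=float(np.clip(a, 0, 1)),
            )
        )
    return dets


def write_detections(detections: list[Detection], path) -> None:
    """One-line-per-box text records: ``class cx cy w h confidence``."""
    with open(path, "w") as fh:
        for d in detections:
            fh.write(f"0 {d.cx:.6f} {d.cy:.6f} {d.w:.6f} {d.h:.6f} {d.confidence:.6f}\n")


def read_detections(path) -> list[Detection]:
    """Parse the one-line-per-box text format written by :func:`write_detections`."""
    dets = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise InputError(f"malformed detection line: {line!r}")
            _, cx, cy, w, h, conf = parts
            dets.append(
                Detection(
                    cx=float(cx), cy=float(cy), w=float(w), h=float(h),
                    confidence=float(conf),
                )
            )
    return dets
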