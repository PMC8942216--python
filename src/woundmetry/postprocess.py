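"""Cleanup of raw segmentation output and repair of missing measurements.

Five techniques are applied downstream of the segmenter:

1. the splint-inner mask keeps only its largest connected component;
2. the wound mask keeps the connected component closest to the crop centre
   among those above a minimum size, discarding false-positive blobs such
   as secondary suture wounds near the splint perimeter;
3. a frame with no detected splint receives the mean splint pixel count of
   all splinted frames in the set;
4. alternatively, it receives the splint count of the splinted frame whose
   wound pixel count is closest to its own — slower, but tracks camera-
   distance variation far better than the global mean;
5. a day with no usable measurement at all is filled with the average of
   its nearest measured neighbours.

Techniques 1-2 operate on 8-bit score maps thresholded at fixed
intensities (wound 20, splint 40); the thresholds and size/centroid
constants live in :class:`PostprocessConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ImputationError, InputError
from .measure import WoundRecord
from .segment import ProbabilityMaps

__all__ = [
    "PostprocessConfig",
    "CleanMasks",
    "threshold_maps",
    "largest_component",
    "select_central_wound",
    "clean_prediction",
    "impute_splint_mean",
    "impute_splint_nearest",
    "fill_missing_timepoints",
]


@dataclass(frozen=True)
class PostprocessConfig:
    """Constants of the mask-cleanup algorithm.

    ``image_centroid`` is the (row, col) point wound candidates are ranked
    against; ``None`` means the centre of the map, which equals the
    conventional (176, 176) on a 352-pixel crop.  ``min_wound_size`` is a
    strict lower bound: components must exceed it to be candidates.
    """

    min_wound_pixel_intensity: int = 20
    min_splint_pixel_intensity: int = 40
    min_wound_size: int = 50
    min_splint_size: int = 50
    image_centroid: tuple[float, float] | None = None
    connectivity: int = 8

    def __post_init__(self) -> None:
        for t in (self.min_wound_pixel_intensity, self.min_splint_pixel_intensity):
            if not 0 <= t <= 255:
                raise InputError(f"intensity thresholds must be in [0, 255], got {t}")
        if self.min_wound_size < 1:
            raise InputError(f"min_wound_size must be >= 1, got {self.min_wound_size}")
        if self.min_splint_size < 0:
            raise InputError(f"min_splint_size must be >= 0, got {self.min_splint_size}")
        if self.connectivity not in (4, 8):
            raise InputError(f"connectivity must be 4 or 8, got {self.connectivity}")

    def centroid_for(self, shape: tuple[int, int]) -> tuple[float, float]:
        if self.image_centroid is not None:
            return self.image_centroid
        return (shape[0] / 2.0, shape[1] / 2.0)


@dataclass
class CleanMasks:
    """Post-processed binary masks for one crop (at most one component each)."""

    wound: np.ndarray
    splint: np.ndarray
    wound_found: bool = True
    splint_found: bool = True

    def __post_init__(self) -> None:
        self.wound = np.asarray(self.wound, dtype=bool)
        self.splint = np.asarray(self.splint, dtype=bool)
        if self.wound.shape != self.splint.shape:
            raise InputError("clean masks must share a shape")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def threshold_maps(
    maps: ProbabilityMaps, config: PostprocessConfig = PostprocessConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Binary wound and splint masks from 8-bit score maps.

    A pixel is included iff its score is >= the class threshold (inclusive).
    """
    wound = np.asarray(maps.wound) >= config.min_wound_pixel_intensity
    splint = np.asarray(maps.splint) >= config.min_splint_pixel_intensity
    return wound, splint


def largest_component(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the connected component with the most pixels.

    Empty input yields empty output.  Size ties are broken toward the
    component containing the earliest pixel in row-major scan order.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        flat = labels.ravel()
        first = [np.argmax(flat == b) for b in best]
        best = [best[int(np.argmin(first))]]
    return labels == best[0]


def select_central_wound(
    mask: np.ndarray, config: PostprocessConfig = PostprocessConfig()
) -> tuple[np.ndarray, bool]:
    """Among components strictly larger than ``min_wound_size``, keep the one
    whose centroid is nearest the image centroid.

    Returns ``(mask, found)``; when no component qualifies the mask is empty
    and ``found`` is False.  Distance ties are broken toward the lower
    component label (earlier in scan order).
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_structure(config.connectivity))
    if n == 0:
        return np.zeros_like(mask), False
    sizes = np.bincount(labels.ravel())[1:]
    candidates = np.flatnonzero(sizes > config.min_wound_size) + 1
    if len(candidates) == 0:
        return np.zeros_like(mask), False
    cy, cx = config.centroid_for(mask.shape)
    centroids = ndimage.center_of_mass(mask, labels, candidates)
    d2 = [(r - cy) ** 2 + (c - cx) ** 2 for r, c in centroids]
    chosen = candidates[int(np.argmin(d2))]
    return labels == chosen, True


def clean_prediction(
    maps: ProbabilityMaps, config: PostprocessConfig = PostprocessConfig()
) -> CleanMasks:
    """Threshold the score maps and apply the component-selection rules.

    The splint keeps its largest component provided it exceeds
    ``min_splint_size`` pixels — a floor that rejects stray boundary
    speckle being mistaken for a reference ring on splint-less frames.
    """
    wound_raw, splint_raw = threshold_maps(maps, config)
    splint = largest_component(splint_raw, config.connectivity)
    if splint.sum() <= config.min_splint_size:
        splint = np.zeros_like(splint)
    wound, wound_found = select_central_wound(wound_raw, config)
    return CleanMasks(
        wound=wound,
        splint=splint,
        wound_found=wound_found,
        splint_found=bool(splint.any()),
    )


def _splinted(records: list[WoundRecord]) -> list[WoundRecord]:
    donors = [r for r in records if r.splint_px is not None and not r.splint_imputed]
    if not donors:
        raise ImputationError("no record has a detected splint; cannot impute")
    return donors


def impute_splint_mean(records: list[WoundRecord]) -> list[WoundRecord]:
    """Technique 3: fill missing splint counts with the set-wide mean.

    Records that already have a splint are returned untouched (same
    objects); filled records are flagged ``splint_imputed``.
    """
    donors = _splinted(records)
    mean_size = float(np.mean([r.splint_px for r in donors]))
    return [
        r
        if r.splint_px is not None
        else replace(r, splint_px=mean_size, splint_imputed=True)
        for r in records
    ]


def impute_splint_nearest(records: list[WoundRecord]) -> list[WoundRecord]:
    """Technique 4: borrow the splint count of the closest-sized wound.

    For each splintless record with a wound measurement, the donor is the
    splinted record whose wound pixel count is nearest; ties go to the donor
    nearest in day, then to the lowest wound_id.  Splintless records with no
    wound count are left for temporal filling.
    """
    donors = _splinted(records)
    out: list[WoundRecord] = []
    for r in records:
        if r.splint_px is not None or r.wound_px is None:
            out.append(r)
            continue
        best = min(
            donors,
            key=lambda d: (
                abs(d.wound_px - r.wound_px) if d.wound_px is not None else np.inf,
                abs(d.day - r.day),
                d.wound_id,
            ),
        )
        out.append(replace(r, splint_px=best.splint_px, splint_imputed=True))
    return out


def fill_missing_timepoints(records: list[WoundRecord]) -> list[WoundRecord]:
    """Technique 5: fill days with no calibrated area from their neighbours.

    An interior missing day receives the mean of the nearest measured (or
    already-filled) previous and next values, applied left to right so runs
    of consecutive gaps fill iteratively; missing leading/trailing days copy
    the nearest measured value.  Filled records are flagged
    ``timepoint_filled``.  Records must be ordered by day.
    """
    if not records:
        raise InputError("cannot fill an empty series")
    days = [r.day for r in records]
    if days != sorted(days) or len(set(days)) != len(days):
        raise InputError("records must be strictly ordered by day")
    values = [r.area_mm2 for r in records]
    if all(v is None for v in values):
        raise InputError("series has no measured day to fill from")

    filled = list(values)
    measured = [i for i, v in enumerate(filled) if v is not None]
    first, last = measured[0], measured[-1]
    for i in range(first):
        filled[i] = filled[first]
    for i in range(last + 1, len(filled)):
        filled[i] = filled[last]
    for i in range(first + 1, last):
        if filled[i] is None:
            nxt = next(j for j in range(i + 1, last + 1) if filled[j] is not None)
            filled[i] = (filled[i - 1] + filled[nxt]) / 2.0
    return [
        r
        if v is not None
        else replace(r, area_mm2=f, timepoint_filled=True)
        for r, v, f in zip(records, values, filled)
    ]
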