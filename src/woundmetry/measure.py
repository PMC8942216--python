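"""Splint-calibrated wound area and closure-percentage time series.

The splint sutured around each wound has a known inner diameter, so the
filled disk bounded by its inner circle serves as an in-frame size
reference.  With ``A_in`` the known inner-disk area in mm² and ``R`` the
ratio of wound pixels to splint-inner pixels in the same photograph, the
unknown wound area is

    A_u = A_in * R.

Because both pixel counts scale identically with camera distance, the
mm-per-pixel factor cancels: the estimate is scale invariant.

Healing progress is summarised as the wound-closure percentage relative to
the day-0 (surgery) area ``A_0``:

    C_P = 100 - (A_i / A_0) * 100,

0 % at day 0, 100 % when fully closed, and negative while the wound is
expanding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import CalibrationError, InputError

__all__ = [
    "SplintGeometry",
    "WoundRecord",
    "WoundSeries",
    "wound_area_mm2",
    "closure_percentage",
    "build_series",
    "average_series",
]


@dataclass(frozen=True)
class SplintGeometry:
    """Physical dimensions of the reference splint, in millimetres.

    The default 10 mm inner / 16 mm outer diameters match the silicone
    rings commonly used in splinted-excisional-wound studies.
    """

    inner_diameter_mm: float = 10.0
    outer_diameter_mm: float = 16.0

    def __post_init__(self) -> None:
        if not (self.outer_diameter_mm > self.inner_diameter_mm > 0):
            raise InputError(
                "splint geometry requires outer_diameter_mm > inner_diameter_mm > 0, "
                f"got inner={self.inner_diameter_mm}, outer={self.outer_diameter_mm}"
            )

    @property
    def inner_area_mm2(self) -> float:
        """Area of the filled inner disk, ``pi * (inner_diameter / 2)**2``."""
        return math.pi * (self.inner_diameter_mm / 2.0) ** 2


def wound_area_mm2(
    wound_px: float,
    splint_px: float,
    geometry: SplintGeometry = SplintGeometry(),
) -> float:
    """Calibrated wound area in mm² from wound and splint-inner pixel counts.

    Raises :class:`CalibrationError` when ``splint_px`` is zero or negative,
    leaving the record uncalibrated so that splint imputation or temporal
    filling can handle it later.
    """
    if wound_px < 0:
        raise InputError(f"wound_px must be >= 0, got {wound_px}")
    if splint_px <= 0:
        raise CalibrationError(
            f"cannot calibrate: splint-inner pixel count is {splint_px}"
        )
    return geometry.inner_area_mm2 * (wound_px / splint_px)


def closure_percentage(a0: float, ai: float) -> float:
    """Wound-closure percentage of day-i area ``ai`` relative to day-0 ``a0``.

    Returns ``100 - 100 * ai / a0``; negative when the wound has expanded
    beyond its day-0 size.
    """
    if a0 <= 0:
        raise InputError(f"day-0 area must be positive, got {a0}")
    if ai < 0:
        raise InputError(f"day-i area must be >= 0, got {ai}")
    return 100.0 - (ai / a0) * 100.0


@dataclass
class WoundRecord:
    """One wound on one day.

    ``wound_px`` / ``splint_px`` are mask pixel counts; either may be
    ``None`` when the stage that produces them failed for that frame
    (no detection, no splint).  ``area_mm2`` is filled in by
    :func:`build_series` once a splint count is available or imputed.
    """

    wound_id: str
    day: int
    wound_px: float | None = None
    splint_px: float | None = None
    area_mm2: float | None = None
    splint_imputed: bool = False
    timepoint_filled: bool = False

    def __post_init__(self) -> None:
        if self.day < 0:
            raise InputError(f"day must be >= 0, got {self.day}")
        for name in ("wound_px", "splint_px", "area_mm2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InputError(f"{name} must be >= 0, got {v}")


@dataclass
class WoundSeries:
    """Ordered day-0..day-N records for one wound plus its closure curve."""

    wound_id: str
    records: list[WoundRecord] = field(default_factory=list)
    day0_area_mm2: float | None = None
    closure_curve: np.ndarray | None = None

    @property
    def days(self) -> np.ndarray:
        return np.array([r.day for r in self.records], dtype=int)

    @property
    def areas_mm2(self) -> np.ndarray:
        return np.array(
            [np.nan if r.area_mm2 is None else r.area_mm2 for r in self.records]
        )


def build_series(
    records: list[WoundRecord],
    imputation: str = "nearest",
    geometry: SplintGeometry = SplintGeometry(),
    day_grid: list[int] | None = None,
) -> WoundSeries:
    """Assemble a closure-percentage series for one wound.

    Applies the chosen splint imputation (``"mean"``, ``"nearest"`` or
    ``"none"``), computes calibrated areas, fills missing timepoints by
    neighbour averaging, and derives the closure curve against the day-0
    area.  ``day_grid`` defaults to ``0..max(day)`` over the input records.
    """
    # Local import: postprocess consumes WoundRecord, so the dependency is
    # inverted at module level and resolved lazily here.
    from . import postprocess

    if not records:
        raise InputError("cannot build a series from zero records")
    wound_ids = {r.wound_id for r in records}
    if len(wound_ids) != 1:
        raise InputError(f"records span multiple wounds: {sorted(wound_ids)}")
    wound_id = records[0].wound_id

    if imputation == "mean":
        records = postprocess.impute_splint_mean(records)
    elif imputation == "nearest":
        records = postprocess.impute_splint_nearest(records)
    elif imputation != "none":
        raise InputError(f"unknown imputation technique {imputation!r}")

    with_area: list[WoundRecord] = []
    for r in records:
        if r.wound_px is not None and r.splint_px is not None and r.splint_px > 0:
            r = replace(
                r, area_mm2=wound_area_mm2(r.wound_px, r.splint_px, geometry)
            )
        with_area.append(r)

    if day_grid is None:
        day_grid = list(range(0, max(r.day for r in with_area) + 1))
    by_day = {r.day: r for r in with_area}
    gridded = [
        by_day.get(d, WoundRecord(wound_id=wound_id, day=d)) for d in day_grid
    ]
    filled = postprocess.fill_missing_timepoints(gridded)

    day0 = next((r for r in filled if r.day == 0), None)
    if day0 is None or day0.area_mm2 is None or day0.area_mm2 <= 0:
        raise InputError(
            f"wound {wound_id}: no positive day-0 area obtainable after filling"
        )
    curve = np.array(
        [closure_percentage(day0.area_mm2, r.area_mm2) for r in filled]
    )
    return WoundSeries(
        wound_id=wound_id,
        records=filled,
        day0_area_mm2=day0.area_mm2,
        closure_curve=curve,
    )


def average_series(series: list[WoundSeries]) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-day arithmetic mean of closure curves across wounds.

    All series must share one day grid.  Returns ``(days, mean_curve, n)``.
    """
    if not series:
        raise InputError("average_series requires at least one series")
    days = series[0].days
    for s in series[1:]:
        if not np.array_equal(s.days, days):
            raise InputError(
                f"series {s.wound_id} day grid differs from {series[0].wound_id}"
            )
    curves = np.stack([s.closure_curve for s in series])
    return days, curves.mean(axis=0), len(series)
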