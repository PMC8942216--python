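"""Segmentation metrics, series statistics, and robustness experiments.

The splint-removal experiment quantifies how well the imputation
techniques hold up when the reference object is absent: splint
measurements are deleted from a cohort either at random (down to a target
availability) or in a fixed window of days, the closure curves are
recomputed with imputation, and the perturbed mean curve is compared with
the baseline one day by day.  The deviation statistic (per-day absolute
difference, summarised as mean and max) is this package's own; the study
design it follows reports curves only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import ImputationError, InputError, UndefinedCorrelationError
from .measure import WoundRecord, WoundSeries, average_series, build_series
from .phantom import PhantomCohort

__all__ = [
    "segmentation_scores",
    "correlation_suite",
    "rmse",
    "records_from_cohort",
    "splint_removal_experiment",
    "RemovalExperimentResult",
]


def segmentation_scores(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Dice and IoU overlap between two binary masks.

    Both are defined as 1 when both masks are empty.  For any pair,
    ``dice = 2 * iou / (1 + iou)``.
    """
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.shape != t.shape:
        raise InputError(f"shape mismatch: {p.shape} vs {t.shape}")
    inter = np.logical_and(p, t).sum()
    union = np.logical_or(p, t).sum()
    total = p.sum() + t.sum()
    if total == 0:
        return 1.0, 1.0
    dice = 2.0 * inter / total
    iou = inter / union
    return float(dice), float(iou)


def correlation_suite(
    curve_x: np.ndarray, curve_y: np.ndarray
) -> tuple[float, float, float]:
    """Pearson, Spearman and Kendall correlation between two curves."""
    x = np.asarray(curve_x, dtype=np.float64)
    y = np.asarray(curve_y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InputError("curves must be 1-D, equal length >= 3")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InputError("curves must not contain missing values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for constant input")
    pearson = stats.pearsonr(x, y).statistic
    spearman = stats.spearmanr(x, y).statistic
    kendall = stats.kendalltau(x, y).statistic
    return float(pearson), float(spearman), float(kendall)


def rmse(series_a: np.ndarray, series_b: np.ndarray) -> float:
    """Root mean square error between two equal-length series."""
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InputError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def records_from_cohort(cohort: PhantomCohort) -> list[WoundRecord]:
    """Ground-truth measurement records for every scene of a phantom cohort.

    Wound pixel counts come from the wound-of-interest component; splint
    counts from the splint-inner mask, absent when the splint is missing.
    """
    records = []
    for s in cohort.scenes:
        splint_px = int(s.splint_inner_mask.sum())
        records.append(
            WoundRecord(
                wound_id=s.wound_id,
                day=s.day,
                wound_px=float(s.params["wound_px"]),
                splint_px=float(splint_px) if splint_px > 0 else None,
            )
        )
    return records


@dataclass
class RemovalExperimentResult:
    """Baseline vs perturbed cohort mean closure curves and their deviation."""

    days: np.ndarray
    baseline_curve: np.ndarray
    perturbed_curve: np.ndarray
    baseline_availability: float
    perturbed_availability: float
    technique: str
    pattern: tuple

    @property
    def deviation(self) -> np.ndarray:
        return np.abs(self.perturbed_curve - self.baseline_curve)

    @property
    def max_deviation(self) -> float:
        return float(self.deviation.max())

    @property
    def mean_deviation(self) -> float:
        return float(self.deviation.mean())


def _mean_curve(records: list[WoundRecord], technique: str) -> tuple[np.ndarray, np.ndarray]:
    by_wound: dict[str, list[WoundRecord]] = {}
    for r in records:
        by_wound.setdefault(r.wound_id, []).append(r)
    n_days = max(r.day for r in records) + 1
    series: list[WoundSeries] = [
        build_series(sorted(recs, key=lambda r: r.day), imputation=technique,
                     day_grid=list(range(n_days)))
        for recs in by_wound.values()
    ]
    days, mean, _ = average_series(series)
    return days, mean


def splint_removal_experiment(
    cohort: PhantomCohort | list[WoundRecord],
    pattern: tuple,
    technique: str = "nearest",
    rng: np.random.Generator | None = None,
) -> RemovalExperimentResult:
    """Remove splint measurements per ``pattern`` and re-run the pipeline tail.

    ``pattern`` is ``("fraction", f)`` — delete splints chosen at random
    until only a fraction ``1 - f`` of all records keep one (records already
    splintless count toward the target) — or ``("window", (a, b))`` —
    delete every splint with day in ``[a, b]``.  Baseline is the cohort's
    native splint availability.  Both runs use the same imputation
    ``technique`` (``"mean"`` or ``"nearest"``).
    """
    records = (
        records_from_cohort(cohort) if isinstance(cohort, PhantomCohort) else list(cohort)
    )
    if rng is None:
        rng = np.random.default_rng()
    n = len(records)
    have = [i for i, r in enumerate(records) if r.splint_px is not None]
    if not have:
        raise ImputationError("cohort has no splinted records at all")

    kind, arg = pattern
    if kind == "fraction":
        target_missing = int(np.floor(arg * n))
        extra = target_missing - (n - len(have))
        if extra >= len(have):
            raise ImputationError("pattern would remove every splint in the cohort")
        drop = set(
            rng.choice(have, size=max(extra, 0), replace=False).tolist()
        )
    elif kind == "window":
        a, b = arg
        drop = {i for i in have if a <= records[i].day <= b}
        if len(drop) == len(have):
            raise ImputationError("pattern would remove every splint in the cohort")
    else:
        raise InputError(f"unknown removal pattern {kind!r}")

    perturbed = [
        replace(r, splint_px=None) if i in drop else r
        for i, r in enumerate(records)
    ]
    days, base = _mean_curve(records, technique)
    _, pert = _mean_curve(perturbed, technique)
    return RemovalExperimentResult(
        days=days,
        baseline_curve=base,
        perturbed_curve=pert,
        baseline_availability=len(have) / n,
        perturbed_availability=(len(have) - len(drop)) / n,
        technique=technique,
        pattern=pattern,
    )
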