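"""Synthetic splinted-wound phantoms with exact ground truth.

Renders flat-colour scenes that emulate the nuisances of real wound
photography — landscape/portrait mix, lighting changes, blur, occluding
tape or hair, satellite wounds, missing or damaged splints, and camera-
distance (mm-per-pixel) variation — while keeping pixel-exact wound and
splint-inner masks as ground truth.  Corruptions are applied to the image
*after* geometry, never to the masks, so the masks always remain truth.

A wound starts as a circular excision (default 6 mm diameter) inside an
annular splint (inner diameter 10 mm, outer 16 mm), expands slightly in the
first days, then contracts to zero by its closure day.  The healing curve is
a two-phase parametric family: linear rise to ``expansion_peak`` at
``expansion_day``, then an exponential-shaped decay reaching exactly zero at
``closure_day``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError
from .measure import SplintGeometry
from .segment import DEFAULT_PALETTE, ProbabilityMaps

__all__ = [
    "HealingParams",
    "CorruptionSpec",
    "PhantomScene",
    "PhantomCohort",
    "healing_fraction",
    "render_phantom",
    "generate_cohort",
    "corrupt_prediction",
    "oracle_maps",
]

#: Shape constant of the post-peak decay (dimensionless); larger = steeper
#: early decline.  Fixed so the curve family stays two-parameter per phase.
_DECAY_SHAPE = 2.0


@dataclass(frozen=True)
class HealingParams:
    """Parameters of one wound's healing trajectory.

    ``noise_sd`` is the standard deviation of multiplicative day-to-day
    area noise applied at render time (the deterministic curve itself is
    noise-free).
    """

    initial_diameter_mm: float = 6.0
    closure_day: float = 14.0
    expansion_peak: float = 1.2
    expansion_day: float = 2.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.initial_diameter_mm <= 0:
            raise InputError("initial_diameter_mm must be positive")
        if self.closure_day <= 0:
            raise InputError("closure_day must be positive")
        if self.expansion_peak < 1.0:
            raise InputError("expansion_peak must be >= 1")
        if not 0 <= self.expansion_day < self.closure_day:
            raise InputError("need 0 <= expansion_day < closure_day")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")


@dataclass(frozen=True)
class CorruptionSpec:
    """Image-level nuisances applied to a rendered scene."""

    lighting_gain: float = 1.0
    blur_sigma: float = 0.0
    occlusion_fraction: float = 0.0
    extra_wound: bool = False
    landscape: bool = False
    missing_splint: bool = False
    false_component_count: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise InputError("occlusion_fraction must be in [0, 1]")
        if self.lighting_gain <= 0:
            raise InputError("lighting_gain must be positive")
        if self.blur_sigma < 0 or self.false_component_count < 0:
            raise InputError("blur_sigma and false_component_count must be >= 0")


@dataclass
class PhantomScene:
    """A rendered phantom image with its exact ground truth."""

    image: np.ndarray
    wound_mask: np.ndarray
    splint_inner_mask: np.ndarray
    bbox: tuple[float, float, float, float, float]  # cx, cy, w, h, confidence
    day: int
    wound_id: str
    splint_present: bool
    params: dict = field(default_factory=dict)


@dataclass
class PhantomCohort:
    """All scenes of a simulated cohort, grouped into per-wound series."""

    scenes: list[PhantomScene]

    @property
    def series(self) -> dict[str, list[PhantomScene]]:
        out: dict[str, list[PhantomScene]] = {}
        for s in self.scenes:
            out.setdefault(s.wound_id, []).append(s)
        for v in out.values():
            v.sort(key=lambda s: s.day)
        return out


def healing_fraction(day: float, params: HealingParams) -> float:
    """Open-area fraction of the day-0 area at ``day``.

    Exactly 1 at day 0, rises linearly to ``expansion_peak`` at
    ``expansion_day``, then decays monotonically (exponential-shaped) to
    exactly 0 at ``closure_day`` and stays 0 afterwards.
    """
    if day < 0:
        raise InputError(f"day must be >= 0, got {day}")
    if day >= params.closure_day:
        return 0.0
    if day <= params.expansion_day:
        if params.expansion_day == 0:
            return 1.0
        t = day / params.expansion_day
        return 1.0 + (params.expansion_peak - 1.0) * t
    u = (day - params.expansion_day) / (params.closure_day - params.expansion_day)
    decay = math.expm1(_DECAY_SHAPE * (1.0 - u)) / math.expm1(_DECAY_SHAPE)
    return params.expansion_peak * decay


def _disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _perturbed_disk(shape, center, radius, amplitudes, phases, modes):
    """Disk whose boundary radius is modulated by low-order Fourier modes."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dy = rr - center[0]
    dx = cc - center[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    bound = radius * (
        1.0
        + sum(
            a * np.cos(k * theta + p)
            for a, p, k in zip(amplitudes, phases, modes)
        )
    )
    return r <= bound


def render_phantom(
    geometry: SplintGeometry,
    healing: HealingParams,
    corruption: CorruptionSpec,
    day: int,
    mm_per_pixel: float,
    rng: np.random.Generator,
    frame_shape: tuple[int, int] | None = None,
    wound_id: str = "C1-M1-L",
    boundary_amplitude: float = 0.05,
    center_jitter: float = 0.03,
) -> PhantomScene:
    """Render one phantom scene at the given day.

    ``frame_shape`` (H, W) defaults to a portrait frame with ~15 % margin
    around the outer splint; ``corruption.landscape`` swaps the axes.  The
    wound boundary is irregular via radial Fourier modes of total amplitude
    at most ``boundary_amplitude`` (fraction of the radius), small enough
    that the analytic disk area remains valid to well under 1 %.
    """
    if mm_per_pixel <= 0:
        raise InputError("mm_per_pixel must be positive")
    s = mm_per_pixel
    r_out = geometry.outer_diameter_mm / 2.0 / s
    r_in = geometry.inner_diameter_mm / 2.0 / s
    if frame_shape is None:
        side = int(math.ceil(2 * r_out * 1.1))
        frame_shape = (int(round(side * 1.15)), side)
    if corruption.landscape and frame_shape[0] > frame_shape[1]:
        frame_shape = (frame_shape[1], frame_shape[0])
    H, W = frame_shape
    if 2 * r_out > min(H, W):
        raise ConfigurationError(
            f"splint (outer diameter {2 * r_out:.0f} px) does not fit in frame {frame_shape}"
        )

    # Centre jitter, bounded so the outer splint stays fully in frame.
    slack_r = H / 2.0 - r_out - 1
    slack_c = W / 2.0 - r_out - 1
    jit = center_jitter * min(H, W)
    center = (
        H / 2.0 + rng.uniform(-1, 1) * min(jit, max(slack_r, 0)),
        W / 2.0 + rng.uniform(-1, 1) * min(jit, max(slack_c, 0)),
    )

    f = healing_fraction(day, healing)
    if healing.noise_sd > 0:
        f *= max(0.0, 1.0 + rng.normal(0.0, healing.noise_sd))
    r_w = (healing.initial_diameter_mm / 2.0 / s) * math.sqrt(f)

    modes = (2, 3)
    amplitudes = rng.uniform(0.0, boundary_amplitude / len(modes), size=len(modes))
    phases = rng.uniform(0.0, 2 * math.pi, size=len(modes))
    if r_w > 0:
        wound = _perturbed_disk(frame_shape, center, r_w, amplitudes, phases, modes)
    else:
        wound = np.zeros(frame_shape, dtype=bool)

    splint_present = not corruption.missing_splint
    if splint_present:
        inner = _disk(frame_shape, center, r_in)
        ring = _disk(frame_shape, center, r_out) & ~inner
    else:
        inner = np.zeros(frame_shape, dtype=bool)
        ring = np.zeros(frame_shape, dtype=bool)

    wound_mask = wound.copy()
    central_px = int(wound.sum())

    if corruption.extra_wound:
        r2 = 0.5 * healing.initial_diameter_mm / 2.0 / s
        placed = False
        for _ in range(50):
            ang = rng.uniform(0, 2 * math.pi)
            d = r_out + r2 + 4
            p = (center[0] + d * math.sin(ang), center[1] + d * math.cos(ang))
            if r2 <= p[0] <= H - 1 - r2 and r2 <= p[1] <= W - 1 - r2:
                wound_mask |= _disk(frame_shape, p, r2)
                placed = True
                break
        if not placed:
            raise ConfigurationError("no room for an extra wound in this frame")

    # --- paint the image from the masks (flat palette colours) ---
    img = np.empty(frame_shape + (3,), dtype=np.float64)
    img[:] = DEFAULT_PALETTE["background"]
    if splint_present:
        img[ring] = DEFAULT_PALETTE["ring"]
        img[inner & ~wound_mask] = DEFAULT_PALETTE["inner_skin"]
    img[wound_mask] = DEFAULT_PALETTE["wound"]

    # Image-level false-positive blobs (e.g. secondary suture wounds around
    # the splint perimeter): wound-coloured, never part of the ground truth.
    blob_r = max(5.0, r_w * 0.25)
    n_false = 0
    for _ in range(corruption.false_component_count):
        for _ in range(80):
            p = (rng.uniform(blob_r, H - 1 - blob_r), rng.uniform(blob_r, W - 1 - blob_r))
            d_center = math.hypot(p[0] - center[0], p[1] - center[1])
            if d_center > r_out + blob_r + 2:
                img[_disk(frame_shape, p, blob_r)] = DEFAULT_PALETTE["wound"]
                n_false += 1
                break

    # --- corruptions (image only) ---
    if corruption.occlusion_fraction > 0 and wound_mask.any():
        rows = np.flatnonzero(wound.any(axis=1))
        cols = np.flatnonzero(wound.any(axis=0))
        if rows.size:
            r0, r1 = rows[0], rows[-1]
            c0, c1 = cols[0], cols[-1]
            rcut = r0 + int(round(corruption.occlusion_fraction * (r1 - r0 + 1)))
            occ = np.zeros(frame_shape, dtype=bool)
            occ[r0:rcut, max(c0 - 3, 0) : c1 + 4] = True
            img[occ] = 0.35 * img[occ] + 0.65 * np.array(
                DEFAULT_PALETTE["occluder"], dtype=np.float64
            )
    if corruption.lighting_gain != 1.0:
        img *= corruption.lighting_gain
    if corruption.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(corruption.blur_sigma,) * 2 + (0,))
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # Bounding box around the wound of interest (including the splint when
    # present), in normalized midpoint coordinates.
    half = r_out if splint_present else max(r_w * 1.2, 1.0)
    bbox = (
        center[1] / W,
        center[0] / H,
        min(2 * half / W, 1.0),
        min(2 * half / H, 1.0),
        1.0,
    )

    return PhantomScene(
        image=img,
        wound_mask=wound_mask,
        splint_inner_mask=inner,
        bbox=bbox,
        day=day,
        wound_id=wound_id,
        splint_present=splint_present,
        params={
            "mm_per_pixel": s,
            "center": center,
            "frame_shape": frame_shape,
            "healing_fraction": f,
            "wound_radius_px": r_w,
            "wound_px": central_px,
            "true_area_mm2": central_px * s * s,
            "false_components": n_false,
        },
    )


def default_healing_sampler(rng: np.random.Generator) -> HealingParams:
    """Per-wound healing parameters with realistic cohort variability."""
    return HealingParams(
        initial_diameter_mm=float(np.clip(rng.normal(6.0, 0.3), 5.0, 7.0)),
        closure_day=float(rng.uniform(12.0, 16.0)),
        expansion_peak=float(rng.uniform(1.05, 1.3)),
        expansion_day=float(rng.uniform(1.0, 3.0)),
        noise_sd=0.02,
    )


def default_corruption_sampler(
    rng: np.random.Generator, day: int
) -> CorruptionSpec:
    """Per-scene nuisance draw mirroring real-photograph variability."""
    return CorruptionSpec(
        lighting_gain=float(rng.uniform(0.85, 1.15)),
        blur_sigma=float(rng.uniform(0.0, 2.0)) if rng.random() < 0.2 else 0.0,
        occlusion_fraction=float(rng.uniform(0.2, 0.5)) if rng.random() < 0.1 else 0.0,
        extra_wound=False,
        landscape=bool(rng.random() < 0.5),
        missing_splint=False,
        false_component_count=int(rng.random() < 0.15),
    )


def generate_cohort(
    n_mice: int,
    n_days: int,
    geometry: SplintGeometry = SplintGeometry(),
    healing_sampler: Callable[[np.random.Generator], HealingParams] | None = None,
    corruption_sampler: Callable[[np.random.Generator, int], CorruptionSpec] | None = None,
    missing_splint_pattern: tuple | None = None,
    rng: np.random.Generator | None = None,
    mm_per_pixel: float = 0.05,
    scale_jitter: float = 0.2,
    cohort: str = "C1",
    frame_shape: tuple[int, int] | None = None,
    boundary_amplitude: float = 0.05,
) -> PhantomCohort:
    """Simulate a cohort: two wounds ("L"/"R") per mouse over ``n_days`` days.

    ``mm_per_pixel`` is jittered per scene by ±``scale_jitter`` to emulate
    camera-distance changes — the quantity the splint calibration must
    cancel.  ``missing_splint_pattern`` is ``None``, ``("fraction", f)``
    (exactly ``floor(f * n_scenes)`` scenes, chosen uniformly, lose their
    splint) or ``("window", (a, b))`` (all scenes with day in [a, b] lose
    it).
    """
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    if n_mice < 1:
        raise ConfigurationError("n_mice must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    healing_sampler = healing_sampler or default_healing_sampler
    corruption_sampler = corruption_sampler or default_corruption_sampler

    wound_ids = [
        f"{cohort}-M{m + 1}-{side}" for m in range(n_mice) for side in ("L", "R")
    ]
    n_scenes = len(wound_ids) * n_days

    missing = np.zeros(n_scenes, dtype=bool)
    if missing_splint_pattern is not None:
        kind, arg = missing_splint_pattern
        if kind == "fraction":
            if not 0.0 <= arg <= 1.0:
                raise ConfigurationError(f"fraction must be in [0, 1], got {arg}")
            k = int(math.floor(arg * n_scenes))
            missing[rng.choice(n_scenes, size=k, replace=False)] = True
        elif kind == "window":
            a, b = arg
            days = np.tile(np.arange(n_days), len(wound_ids))
            missing = (days >= a) & (days <= b)
        else:
            raise ConfigurationError(f"unknown missing-splint pattern {kind!r}")

    scenes: list[PhantomScene] = []
    idx = 0
    for wid in wound_ids:
        healing = healing_sampler(rng)
        for day in range(n_days):
            corr = corruption_sampler(rng, day)
            corr = replace(corr, missing_splint=bool(missing[idx]))
            s = mm_per_pixel * rng.uniform(1 - scale_jitter, 1 + scale_jitter)
            scenes.append(
                render_phantom(
                    geometry,
                    healing,
                    corr,
                    day,
                    s,
                    rng,
                    frame_shape=frame_shape,
                    wound_id=wid,
                    boundary_amplitude=boundary_amplitude,
                )
            )
            idx += 1
    return PhantomCohort(scenes=scenes)


def save_cohort(cohort: PhantomCohort, out_dir) -> None:
    """Write a cohort in the pipeline's on-disk input format.

    Per scene: ``<stem>.png`` (image), ``<stem>_label.png`` (8-bit label
    mask: 0 background, 1 wound, 2 splint-inner; wound wins where the
    regions overlap) and ``<stem>.json`` (LabelMe-style polygons).  A
    ``manifest.csv`` lists (filename, wound_id, day, splint_present,
    true_area_mm2, mm_per_pixel).
    """
    import csv
    from pathlib import Path

    from PIL import Image

    from .annotations import mask_to_polygons, write_annotation_document

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.scenes:
        stem = f"{s.wound_id}_day{s.day:02d}"
        Image.fromarray(s.image).save(out / f"{stem}.png")
        label = np.zeros(s.wound_mask.shape, dtype=np.uint8)
        label[s.splint_inner_mask] = 2
        label[s.wound_mask] = 1
        Image.fromarray(label).save(out / f"{stem}_label.png")
        polys = mask_to_polygons(s.wound_mask, "wound") + mask_to_polygons(
            s.splint_inner_mask, "splint"
        )
        write_annotation_document(polys, out / f"{stem}.json", image_path=f"{stem}.png")
        rows.append(
            {
                "filename": f"{stem}.png",
                "wound_id": s.wound_id,
                "day": s.day,
                "splint_present": s.splint_present,
                "true_area_mm2": f"{s.params['true_area_mm2']:.4f}",
                "mm_per_pixel": f"{s.params['mm_per_pixel']:.6f}",
            }
        )
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def oracle_maps(scene: PhantomScene) -> ProbabilityMaps:
    """Ground-truth masks of a scene as 8-bit score maps (a perfect segmenter)."""
    return ProbabilityMaps(
        wound=scene.wound_mask.astype(np.uint8) * 255,
        splint=scene.splint_inner_mask.astype(np.uint8) * 255,
    )


def corrupt_prediction(
    masks,
    false_component_count: int,
    rng: np.random.Generator,
    noise_fraction: float = 0.01,
    component_area: float = 80.0,
) -> ProbabilityMaps:
    """Turn clean masks into a deliberately dirty prediction.

    The wound channel gains ``false_component_count`` off-centre disks of
    at least ``component_area`` pixels (disjoint from the true wound and
    farther from the map centre) plus salt noise strictly below the wound
    threshold of 20; the splint channel gains salt noise below its
    threshold of 40.  With no injected components and no noise the maps
    threshold back to the input masks exactly.
    """
    if hasattr(masks, "wound"):
        wound = np.asarray(masks.wound, dtype=bool)
        splint = np.asarray(masks.splint, dtype=bool)
    else:
        wound = np.asarray(masks[0], dtype=bool)
        splint = np.asarray(masks[1], dtype=bool)
    H, W = wound.shape
    wmap = wound.astype(np.uint8) * 255
    smap = splint.astype(np.uint8) * 255

    center = (H / 2.0, W / 2.0)
    if wound.any():
        rr, cc = np.nonzero(wound)
        true_reach = float(np.hypot(rr - center[0], cc - center[1]).max())
    else:
        true_reach = 0.0
    blob_r = math.sqrt(component_area / math.pi) + 1.0

    placed = 0
    attempts = 0
    while placed < false_component_count and attempts < 500:
        attempts += 1
        p = (rng.uniform(blob_r, H - 1 - blob_r), rng.uniform(blob_r, W - 1 - blob_r))
        if math.hypot(p[0] - center[0], p[1] - center[1]) <= true_reach + blob_r + 3:
            continue
        blob = _disk((H, W), p, blob_r)
        if (wmap[blob] > 0).any():
            continue
        wmap[blob] = 255
        placed += 1
    if placed < false_component_count:
        raise ConfigurationError(
            f"could only place {placed}/{false_component_count} false components"
        )

    if noise_fraction > 0:
        for chan, lim in ((wmap, 20), (smap, 40)):
            zeros = np.flatnonzero(chan == 0)
            k = int(noise_fraction * zeros.size)
            if k:
                picks = rng.choice(zeros, size=k, replace=False)
                chan.ravel()[picks] = rng.integers(1, lim, size=k)
    return ProbabilityMaps(wound=wmap, splint=smap)
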