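"""Phantom generator: healing curve, rendering, cohorts, dirty predictions."""

import numpy as np
import pytest

from woundmetry.errors import ConfigurationError, InputError
from woundmetry.measure import SplintGeometry, wound_area_mm2
from woundmetry.phantom import (
    CorruptionSpec,
    HealingParams,
    corrupt_prediction,
    generate_cohort,
    healing_fraction,
    render_phantom,
)
from woundmetry.postprocess import CleanMasks

from _oracles import bfs_components


class TestHealingFraction:
    def test_day_zero_is_exactly_one(self):
        for params in (HealingParams(), HealingParams(expansion_peak=1.5)):
            assert healing_fraction(0, params) == 1.0

    def test_closed_after_closure_day(self):
        p = HealingParams(closure_day=14)
        assert healing_fraction(19, p) == 0.0
        assert healing_fraction(14, p) == 0.0

    def test_peak_value_at_expansion_day(self):
        p = HealingParams(expansion_peak=1.2, expansion_day=2)
        assert healing_fraction(2, p) == pytest.approx(1.2)

    def test_monotone_decreasing_after_peak(self):
        p = HealingParams(expansion_peak=1.3, expansion_day=3, closure_day=15)
        days = np.linspace(3, 15, 60)
        vals = [healing_fraction(d, p) for d in days]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_negative_day_rejected(self):
        with pytest.raises(InputError):
            healing_fraction(-1, HealingParams())


class TestRenderPhantom:
    def test_day0_wound_pixel_count_matches_disk_area(self, rng):
        scene = render_phantom(
            SplintGeometry(), HealingParams(noise_sd=0.0), CorruptionSpec(),
            day=0, mm_per_pixel=0.05, rng=rng,
        )
        expected = np.pi * 3.0**2 / 0.05**2
        assert scene.wound_mask.sum() == pytest.approx(expected, rel=0.02)

    def test_missing_splint_flag_and_empty_mask(self, rng):
        scene = render_phantom(
            SplintGeometry(), HealingParams(), CorruptionSpec(missing_splint=True),
            day=0, mm_per_pixel=0.1, rng=rng,
        )
        assert not scene.splint_present
        assert scene.splint_inner_mask.sum() == 0

    def test_extra_wound_gives_two_components_off_center_farther(self, rng):
        scene = render_phantom(
            SplintGeometry(), HealingParams(), CorruptionSpec(extra_wound=True),
            day=0, mm_per_pixel=0.1, rng=rng,
        )
        comps = bfs_components(scene.wound_mask.tolist())
        assert len(comps) == 2
        H, W = scene.wound_mask.shape
        dists = sorted(
            np.hypot(
                np.mean([r for r, _ in comp]) - H / 2,
                np.mean([c for _, c in comp]) - W / 2,
            )
            for comp in comps
        )
        # satellite wound lies beyond the splint's outer radius
        assert dists[1] > 8.0 / 0.1

    def test_mask_containment_when_splinted_and_unoccluded(self, rng):
        scene = render_phantom(
            SplintGeometry(), HealingParams(), CorruptionSpec(),
            day=2, mm_per_pixel=0.1, rng=rng,
        )
        assert not (scene.wound_mask & ~scene.splint_inner_mask).any()

    def test_identical_seed_gives_bit_identical_scene(self):
        args = (SplintGeometry(), HealingParams(), CorruptionSpec(blur_sigma=1.0))
        a = render_phantom(*args, day=3, mm_per_pixel=0.08, rng=np.random.default_rng(42))
        b = render_phantom(*args, day=3, mm_per_pixel=0.08, rng=np.random.default_rng(42))
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.wound_mask, b.wound_mask)

    def test_splint_must_fit_in_frame(self, rng):
        with pytest.raises(ConfigurationError):
            render_phantom(
                SplintGeometry(), HealingParams(), CorruptionSpec(),
                day=0, mm_per_pixel=0.05, rng=rng, frame_shape=(100, 100),
            )

    def test_true_area_equals_pixel_count_times_scale_squared(self, rng):
        scene = render_phantom(
            SplintGeometry(), HealingParams(), CorruptionSpec(),
            day=1, mm_per_pixel=0.07, rng=rng,
        )
        assert scene.params["true_area_mm2"] == pytest.approx(
            scene.wound_mask.sum() * 0.07**2
        )


class TestGenerateCohort:
    def test_counts_two_wounds_per_mouse(self, full_cohort):
        assert len(full_cohort.scenes) == 4 * 2 * 16
        assert len(full_cohort.series) == 8
        for scenes in full_cohort.series.values():
            assert [s.day for s in scenes] == list(range(16))

    def test_fraction_pattern_flags_exact_count(self):
        coh = generate_cohort(
            4, 16, missing_splint_pattern=("fraction", 0.25),
            rng=np.random.default_rng(3), mm_per_pixel=0.15,
        )
        n_missing = sum(not s.splint_present for s in coh.scenes)
        assert n_missing == int(0.25 * 128)

    def test_window_pattern_removes_whole_days(self):
        coh = generate_cohort(
            1, 16, missing_splint_pattern=("window", (0, 7)),
            rng=np.random.default_rng(3), mm_per_pixel=0.15,
        )
        for s in coh.scenes:
            assert s.splint_present == (s.day > 7)

    def test_ground_truth_conservation_through_calibration(self, benign_cohort):
        # calibrated area from ground-truth masks must recover the
        # generator's true open area (pixel discretization only)
        for s in benign_cohort.scenes:
            if not s.splint_present or s.wound_mask.sum() == 0:
                continue
            est = wound_area_mm2(s.wound_mask.sum(), s.splint_inner_mask.sum())
            assert est == pytest.approx(s.params["true_area_mm2"], rel=0.02)

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(
                1, 4, missing_splint_pattern=("bogus", 1),
                rng=np.random.default_rng(0), mm_per_pixel=0.15,
            )


class TestCorruptPrediction:
    @staticmethod
    def _masks(shape=(96, 96)):
        yy, xx = np.ogrid[: shape[0], : shape[1]]
        wound = (yy - 48) ** 2 + (xx - 48) ** 2 <= 12**2
        splint = (yy - 48) ** 2 + (xx - 48) ** 2 <= 30**2
        return CleanMasks(wound=wound, splint=splint)

    def test_round_trip_without_injection(self, rng):
        masks = self._masks()
        maps = corrupt_prediction(masks, 0, rng, noise_fraction=0.0)
        assert np.array_equal(maps.wound >= 20, masks.wound)
        assert np.array_equal(maps.splint >= 40, masks.splint)

    def test_injected_components_counted(self, rng):
        maps = corrupt_prediction(self._masks(), 2, rng)
        comps = bfs_components((np.asarray(maps.wound) >= 20).tolist())
        assert len(comps) == 3
        assert all(len(c) >= 50 for c in comps)

    def test_salt_noise_stays_below_thresholds(self, rng):
        masks = self._masks()
        maps = corrupt_prediction(masks, 0, rng, noise_fraction=0.05)
        assert np.array_equal(maps.wound >= 20, masks.wound)
        assert np.array_equal(maps.splint >= 40, masks.splint)
        assert (np.asarray(maps.wound) > 0).sum() > masks.wound.sum()
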