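"""Overlap metrics, correlation suite, RMSE, splint-removal experiments."""

import numpy as np
import pytest

from woundmetry.errors import ImputationError, InputError, UndefinedCorrelationError
from woundmetry.evaluate import (
    correlation_suite,
    records_from_cohort,
    rmse,
    segmentation_scores,
    splint_removal_experiment,
)
from woundmetry.phantom import HealingParams, generate_cohort


class TestSegmentationScores:
    def test_identical_masks(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2:7, 2:7] = True
        assert segmentation_scores(m, m) == (1.0, 1.0)

    def test_disjoint_masks(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[0, 0] = True
        b[5, 5] = True
        assert segmentation_scores(a, b) == (0.0, 0.0)

    def test_half_overlap_values(self):
        a = np.zeros((20, 20), dtype=bool)
        b = np.zeros((20, 20), dtype=bool)
        a[0:10, 0:10] = True  # 100 px
        b[0:10, 5:15] = True  # 100 px, 50 shared
        dice, iou = segmentation_scores(a, b)
        assert dice == pytest.approx(0.5)
        assert iou == pytest.approx(1.0 / 3.0)

    def test_both_empty_defined_as_one(self):
        e = np.zeros((4, 4), dtype=bool)
        assert segmentation_scores(e, e) == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_dice_iou_identity_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16)) < 0.4
        b = rng.random((16, 16)) < 0.4
        dice, iou = segmentation_scores(a, b)
        assert segmentation_scores(b, a) == (dice, iou)
        assert dice == pytest.approx(2 * iou / (1 + iou))


class TestCorrelationSuite:
    def test_identical_curves(self):
        x = np.array([1.0, 3.0, 7.0, 9.0])
        assert correlation_suite(x, x) == pytest.approx((1.0, 1.0, 1.0))

    def test_reversed_ranking(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        p, s, k = correlation_suite(x, x[::-1])
        assert s == pytest.approx(-1.0)
        assert k == pytest.approx(-1.0)

    def test_monotone_nonlinear(self):
        p, s, k = correlation_suite([1, 2, 3, 5], [1, 2, 4, 8])
        assert s == pytest.approx(1.0)
        assert k == pytest.approx(1.0)
        assert p < 1.0

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            correlation_suite([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRmse:
    def test_identical_is_zero(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_closed_form(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        a, b = rng.normal(size=n), rng.normal(size=n)
        acc = 0.0
        for x, y in zip(a, b):
            acc += (x - y) ** 2
        assert rmse(a, b) == pytest.approx((acc / n) ** 0.5)

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            rmse([1.0], [1.0, 2.0])


class TestSplintRemovalExperiment:
    def test_zero_fraction_is_identity(self, full_cohort):
        res = splint_removal_experiment(
            full_cohort, ("fraction", 0.0), "nearest", np.random.default_rng(0)
        )
        assert np.array_equal(res.baseline_curve, res.perturbed_curve)
        assert res.max_deviation == 0.0

    def test_window_removes_half_the_frames(self, full_cohort):
        res = splint_removal_experiment(
            full_cohort, ("window", (0, 7)), "nearest", np.random.default_rng(0)
        )
        assert res.perturbed_availability == pytest.approx(
            res.baseline_availability - 0.5
        )

    def test_reproducible_under_fixed_seed(self, full_cohort):
        a = splint_removal_experiment(
            full_cohort, ("fraction", 0.4), "nearest", np.random.default_rng(5)
        )
        b = splint_removal_experiment(
            full_cohort, ("fraction", 0.4), "nearest", np.random.default_rng(5)
        )
        assert np.array_equal(a.perturbed_curve, b.perturbed_curve)

    def test_removing_everything_impossible(self, full_cohort):
        with pytest.raises(ImputationError):
            splint_removal_experiment(
                full_cohort, ("fraction", 1.0), "mean", np.random.default_rng(0)
            )

    def test_deviation_trend_grows_with_fraction(self):
        # expectation over seeds: heavier removal cannot help
        lo, hi = [], []
        for seed in range(6):
            coh = generate_cohort(
                2, 8, rng=np.random.default_rng(400 + seed), mm_per_pixel=0.15
            )
            lo.append(
                splint_removal_experiment(
                    coh, ("fraction", 0.15), "mean", np.random.default_rng(seed)
                ).mean_deviation
            )
            hi.append(
                splint_removal_experiment(
                    coh, ("fraction", 0.5), "mean", np.random.default_rng(seed)
                ).mean_deviation
            )
        assert np.mean(hi) > np.mean(lo)

    def test_nearest_beats_mean_under_camera_distance_variation(self):
        # the regime size-matched imputation exists for: healing-stage
        # differences small, camera distance the dominant source of pixel-
        # count variation
        def slow_healer(rng):
            return HealingParams(
                initial_diameter_mm=float(rng.normal(6.0, 0.3)),
                closure_day=300.0, expansion_peak=1.0, expansion_day=1.0,
                noise_sd=0.02,
            )

        near, mean = [], []
        for seed in range(20):
            coh = generate_cohort(
                3, 8, healing_sampler=slow_healer,
                rng=np.random.default_rng(300 + seed), mm_per_pixel=0.15,
            )
            near.append(
                splint_removal_experiment(
                    coh, ("fraction", 0.5), "nearest", np.random.default_rng(seed)
                ).mean_deviation
            )
            mean.append(
                splint_removal_experiment(
                    coh, ("fraction", 0.5), "mean", np.random.default_rng(seed)
                ).mean_deviation
            )
        assert np.mean(near) <= np.mean(mean)

    def test_records_from_cohort_flags_missing_splints(self):
        coh = generate_cohort(
            1, 6, missing_splint_pattern=("window", (2, 3)),
            rng=np.random.default_rng(8), mm_per_pixel=0.15,
        )
        records = records_from_cohort(coh)
        for r in records:
            assert (r.splint_px is None) == (r.day in (2, 3))
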