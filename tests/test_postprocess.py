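"""Mask cleanup (thresholds, component selection), imputation, gap filling."""

import numpy as np
import pytest

from woundmetry.errors import ImputationError, InputError
from woundmetry.measure import WoundRecord
from woundmetry.phantom import corrupt_prediction
from woundmetry.postprocess import (
    CleanMasks,
    PostprocessConfig,
    clean_prediction,
    fill_missing_timepoints,
    impute_splint_mean,
    impute_splint_nearest,
    largest_component,
    select_central_wound,
    threshold_maps,
)
from woundmetry.segment import ProbabilityMaps

from _oracles import central_wound_brute_force, largest_component_brute_force


def maps_from(wound, splint=None):
    wound = np.asarray(wound, dtype=np.uint8)
    if splint is None:
        splint = np.zeros_like(wound)
    return ProbabilityMaps(wound=wound, splint=np.asarray(splint, dtype=np.uint8))


class TestThresholdMaps:
    def test_inclusive_at_wound_threshold(self):
        wound = np.array([[20, 19], [0, 255]])
        w, _ = threshold_maps(maps_from(wound))
        assert w.tolist() == [[True, False], [False, True]]

    def test_splint_threshold_40(self):
        splint = np.array([[39, 40]])
        _, s = threshold_maps(maps_from(np.zeros((1, 2)), splint))
        assert s.tolist() == [[False, True]]

    def test_all_zero_maps_empty(self):
        w, s = threshold_maps(maps_from(np.zeros((4, 4))))
        assert not w.any() and not s.any()


class TestLargestComponent:
    def test_keeps_biggest(self):
        mask = np.zeros((20, 40), dtype=bool)
        mask[2:14, 2:12] = True  # 120 px
        mask[2:10, 30:35] = True  # 40 px
        out = largest_component(mask)
        assert out.sum() == 120
        assert out[:, :12].sum() == 120

    def test_empty_in_empty_out(self):
        assert not largest_component(np.zeros((8, 8), dtype=bool)).any()

    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert largest_component(mask, connectivity=8).sum() == 2
        assert largest_component(mask, connectivity=4).sum() == 1

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_bfs_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 12)) < 0.35
        out = largest_component(mask, connectivity)
        oracle = largest_component_brute_force(mask.tolist(), connectivity)
        assert set(zip(*np.nonzero(out))) == oracle


class TestSelectCentralWound:
    def test_central_beats_peripheral(self):
        mask = np.zeros((352, 352), dtype=bool)
        mask[160:192, 160:192] = True  # centred, 1024 px
        mask[20:60, 20:60] = True  # peripheral, 1600 px
        out, found = select_central_wound(mask, PostprocessConfig(image_centroid=(176, 176)))
        assert found
        assert out[176, 176] and not out[30, 30]

    def test_component_at_exactly_min_size_rejected(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:25, 20:30] = True  # exactly 50 px
        out, found = select_central_wound(mask, PostprocessConfig(min_wound_size=50))
        assert not found and not out.any()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        mask = rng.random((32, 32)) < 0.3
        cfg = PostprocessConfig(min_wound_size=3)
        out, found = select_central_wound(mask, cfg)
        oracle = central_wound_brute_force(mask.tolist(), 3, (16.0, 16.0))
        assert set(zip(*np.nonzero(out))) == oracle
        assert found == bool(oracle)


class TestCleanPrediction:
    def test_recovers_truth_from_corrupted_prediction(self, rng):
        wound = np.zeros((128, 128), dtype=bool)
        yy, xx = np.ogrid[:128, :128]
        wound |= (yy - 64) ** 2 + (xx - 64) ** 2 <= 15**2
        splint = (yy - 64) ** 2 + (xx - 64) ** 2 <= 40**2
        dirty = corrupt_prediction(CleanMasks(wound=wound, splint=splint), 2, rng)
        clean = clean_prediction(dirty)
        assert np.array_equal(clean.wound, wound)
        assert np.array_equal(clean.splint, splint)

    def test_splintless_maps_flag(self):
        wound = np.zeros((128, 128), dtype=np.uint8)
        wound[50:80, 50:80] = 255
        clean = clean_prediction(maps_from(wound))
        assert clean.wound_found and not clean.splint_found

    def test_idempotent_on_clean_masks(self, rng):
        wound = np.zeros((96, 96), dtype=bool)
        wound[40:60, 40:60] = True
        splint = np.zeros((96, 96), dtype=bool)
        splint[20:80, 20:80] = True
        once = clean_prediction(
            ProbabilityMaps(wound=wound * np.uint8(255), splint=splint * np.uint8(255))
        )
        again = clean_prediction(
            ProbabilityMaps(
                wound=once.wound.astype(np.uint8) * 255,
                splint=once.splint.astype(np.uint8) * 255,
            )
        )
        assert np.array_equal(once.wound, again.wound)
        assert np.array_equal(once.splint, again.splint)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_increases_pixel_count(self, seed):
        rng = np.random.default_rng(seed)
        maps = maps_from(
            rng.integers(0, 256, (64, 64)), rng.integers(0, 256, (64, 64))
        )
        raw_w, raw_s = threshold_maps(maps)
        clean = clean_prediction(maps)
        assert clean.wound.sum() <= raw_w.sum()
        assert clean.splint.sum() <= raw_s.sum()


def rec(day, wound_px=None, splint_px=None, wid="W", **kw):
    return WoundRecord(wound_id=wid, day=day, wound_px=wound_px, splint_px=splint_px, **kw)


class TestImputeSplintMean:
    def test_mean_of_available(self):
        records = [rec(0, 900, 4000.0), rec(1, 800, 5000.0), rec(2, 700, None)]
        out = impute_splint_mean(records)
        assert out[2].splint_px == 4500.0
        assert out[2].splint_imputed

    def test_no_missing_is_identity(self):
        records = [rec(0, 900, 4000.0), rec(1, 800, 5000.0)]
        assert impute_splint_mean(records) == records

    def test_splinted_records_kept_identical(self):
        records = [rec(0, 900, 4000.0), rec(1, 700, None)]
        out = impute_splint_mean(records)
        assert out[0] is records[0]

    def test_all_missing_impossible(self):
        with pytest.raises(ImputationError):
            impute_splint_mean([rec(0, 900, None)])


class TestImputeSplintNearest:
    def test_nearest_wound_size_donor(self):
        records = [rec(0, 1000, 4000.0), rec(1, 2000, 5000.0), rec(2, 1200, None)]
        out = impute_splint_nearest(records)
        assert out[2].splint_px == 4000.0
        assert out[2].splint_imputed

    def test_tie_broken_toward_nearest_day(self):
        records = [
            rec(3, 1000, 4000.0),
            rec(9, 2000, 5000.0),
            rec(4, 1500, None),  # exactly between donors; day 3 is closer
        ]
        out = impute_splint_nearest(records)
        assert out[2].splint_px == 4000.0

    def test_single_donor_used_for_all(self):
        records = [rec(0, 1000, 4200.0), rec(1, 1000, None), rec(2, 1000, None)]
        out = impute_splint_nearest(records)
        assert out[1].splint_px == out[2].splint_px == 4200.0

    def test_deterministic(self):
        records = [rec(0, 1000, 4000.0), rec(1, 1800, 5000.0), rec(2, 1500, None)]
        assert impute_splint_nearest(records) == impute_splint_nearest(records)


class TestFillMissingTimepoints:
    @staticmethod
    def series(areas):
        return [
            WoundRecord(wound_id="W", day=d, area_mm2=a)
            for d, a in enumerate(areas)
        ]

    def test_interior_gap_mean_of_neighbours(self):
        out = fill_missing_timepoints(self.series([10.0, None, 20.0]))
        assert [r.area_mm2 for r in out] == [10.0, 15.0, 20.0]
        assert [r.timepoint_filled for r in out] == [False, True, False]

    def test_run_of_gaps_fills_left_to_right(self):
        out = fill_missing_timepoints(self.series([10.0, None, None, 20.0]))
        assert [r.area_mm2 for r in out] == [10.0, 15.0, 17.5, 20.0]

    def test_leading_and_trailing_copy_nearest(self):
        out = fill_missing_timepoints(self.series([None, 12.0, None]))
        assert [r.area_mm2 for r in out] == [12.0, 12.0, 12.0]
        assert [r.timepoint_filled for r in out] == [True, False, True]

    def test_no_missing_is_identity(self):
        records = self.series([10.0, 11.0])
        assert fill_missing_timepoints(records) == records

    def test_empty_series_rejected(self):
        with pytest.raises(InputError):
            fill_missing_timepoints([])
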