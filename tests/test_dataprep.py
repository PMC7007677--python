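"""Cropping, mirror padding, tile extraction/stitching and the ranked split."""

import numpy as np
import pytest

from rootseg import dataprep
from rootseg.dataprep import StitchError, TilePair


class TestCrop:
    def test_native_size_crops_to_analysis_region(self):
        img = np.zeros((2592, 4608, 3), dtype=np.uint8)
        img[375, 0, 0] = 7  # first kept row
        img[:, 3990, 1] = 9  # last kept column
        out = dataprep.crop_to_analysis_region(img)
        assert out.shape == (1842, 3991, 3)
        assert out[0, 0, 0] == 7
        assert (out[:, 3990, 1] == 9).all()

    def test_rows_split_evenly_columns_from_right(self):
        img = np.arange(2592 * 4608, dtype=np.int32).reshape(2592, 4608)
        out = dataprep.crop_to_analysis_region(img)
        np.testing.assert_array_equal(out, img[375 : 375 + 1842, :3991])

    def test_exact_size_is_noop(self):
        img = np.zeros((1842, 3991), dtype=np.uint8)
        out = dataprep.crop_to_analysis_region(img)
        assert out.shape == (1842, 3991)
        np.testing.assert_array_equal(out, img)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            dataprep.crop_to_analysis_region(np.zeros((100, 100)))


class TestMirrorPad:
    def test_reflection_without_edge_repeat(self):
        out = dataprep.mirror_pad(np.array([1, 2, 3]), 2)
        np.testing.assert_array_equal(out, [3, 2, 1, 2, 3, 2, 1])

    def test_zero_margin_identity(self):
        img = np.arange(12).reshape(3, 4)
        assert dataprep.mirror_pad(img, 0) is img

    @pytest.mark.parametrize("shape", [(5, 7), (5, 7, 3)])
    def test_size_contract_and_interior_unchanged(self, shape):
        img = np.random.default_rng(0).integers(0, 255, shape).astype(np.uint8)
        out = dataprep.mirror_pad(img, 3)
        assert out.shape[:2] == (shape[0] + 6, shape[1] + 6)
        np.testing.assert_array_equal(out[3:-3, 3:-3], img)

    def test_margin_too_large_raises(self):
        with pytest.raises(ValueError):
            dataprep.mirror_pad(np.zeros((4, 4)), 4)


class TestInstanceSelection:
    def _image(self, h, w):
        return np.zeros((h, w, 3), dtype=np.uint8)

    def test_all_root_mask_hits_cap(self):
        mask = np.ones((300, 300), dtype=np.uint8)
        tiles = dataprep.sample_training_tiles(
            self._image(300, 300), mask, n_candidates=90, cap=40, seed=0, out_side=64
        )
        assert len(tiles) == 40

    def test_all_background_gives_no_tiles(self):
        mask = np.zeros((300, 300), dtype=np.uint8)
        tiles = dataprep.sample_training_tiles(
            self._image(300, 300), mask, seed=0, out_side=64
        )
        assert tiles == []

    def test_ninety_candidates_drawn_before_filtering(self):
        # with an uncapped selection on an all-root mask every candidate
        # survives, exposing the candidate count (duplicates allowed)
        mask = np.ones((300, 300), dtype=np.uint8)
        tiles = dataprep.sample_training_tiles(
            self._image(300, 300), mask, n_candidates=90, cap=10**9, seed=1, out_side=64
        )
        assert len(tiles) == 90

    def test_every_tile_contains_roots_and_geometry_holds(self):
        rng = np.random.default_rng(2)
        mask = (rng.uniform(size=(300, 300)) < 0.001).astype(np.uint8)
        tiles = dataprep.sample_training_tiles(
            self._image(300, 300), mask, seed=3, out_side=64
        )
        assert len(tiles) <= 40
        for t in tiles:
            assert t.target_patch.any()
            assert t.input_patch.shape[0] - t.target_patch.shape[0] == 184
            assert t.input_patch.shape[1] - t.target_patch.shape[1] == 184

    def test_deterministic_in_seed(self):
        rng = np.random.default_rng(4)
        mask = (rng.uniform(size=(300, 300)) < 0.01).astype(np.uint8)
        a = dataprep.sample_training_tiles(self._image(300, 300), mask, seed=5, out_side=64)
        b = dataprep.sample_training_tiles(self._image(300, 300), mask, seed=5, out_side=64)
        assert [t.origin for t in a] == [t.origin for t in b]

    def test_tile_pair_geometry_invariant_enforced(self):
        with pytest.raises(ValueError):
            TilePair(
                input_patch=np.zeros((100, 100, 3)),
                target_patch=np.zeros((50, 50)),
                origin=(0, 0),
            )


class TestInferenceTiling:
    def _padded(self, h, w):
        return np.zeros((h + 184, w + 184, 3), dtype=np.uint8)

    def test_single_tile_image(self):
        tiles = dataprep.inference_tiles(self._padded(388, 388), out_side=388)
        assert len(tiles) == 1
        assert tiles[0].origin == (0, 0)
        assert tiles[0].input_patch.shape[:2] == (572, 572)

    def test_two_stacked_tiles(self):
        tiles = dataprep.inference_tiles(self._padded(776, 388), out_side=388)
        assert [t.origin for t in tiles] == [(0, 0), (388, 0)]

    def test_edge_tiles_shift_inward(self):
        tiles = dataprep.inference_tiles(self._padded(400, 400), out_side=388)
        assert [t.origin for t in tiles] == [(0, 0), (0, 12), (12, 0), (12, 12)]

    def test_output_regions_cover_image(self):
        tiles = dataprep.inference_tiles(self._padded(500, 900), out_side=388)
        cover = np.zeros((500, 900), dtype=bool)
        for t in tiles:
            r, c = t.origin
            cover[r : r + 388, c : c + 388] = True
        assert cover.all()

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError):
            dataprep.inference_tiles(self._padded(100, 100), out_side=388)


class TestStitch:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        full = rng.uniform(size=(100, 160))
        tiles = []
        for r in range(0, 100, 50):
            for c in range(0, 160, 40):
                tiles.append(((r, c), full[r : r + 50, c : c + 40]))
        out = dataprep.stitch_predictions(tiles, 100, 160)
        np.testing.assert_array_equal(out, full)

    def test_overlap_takes_later_tile(self):
        tiles = [((0, 0), np.zeros((4, 4))), ((0, 2), np.ones((4, 2)))]
        out = dataprep.stitch_predictions(tiles, 4, 4)
        assert (out[:, 2:] == 1).all() and (out[:, :2] == 0).all()

    def test_missing_tile_names_coordinate(self):
        tiles = [((0, 0), np.ones((4, 4)))]
        with pytest.raises(StitchError, match=r"\(0, 4\)"):
            dataprep.stitch_predictions(tiles, 4, 8)


class TestSplit:
    def test_38_images_give_29_train_9_val(self):
        counts = [(f"img{i:02d}", i * 137 % 3001) for i in range(38)]
        split = dataprep.split_train_val(counts, n_val=9)
        assert len(split.train_ids) == 29
        assert len(split.val_ids) == 9
        assert not set(split.train_ids) & set(split.val_ids)
        assert set(split.train_ids) | set(split.val_ids) == {c[0] for c in counts}

    def test_even_spacing_picks_both_extremes(self):
        counts = list(zip("abcde", [10, 20, 30, 40, 50]))
        split = dataprep.split_train_val(counts, n_val=2)
        assert split.val_ids == ["a", "e"]

    def test_both_subsets_span_count_range(self):
        counts = [(i, c) for i, c in enumerate(range(0, 380, 10))]
        split = dataprep.split_train_val(counts, n_val=9)
        ranked = [i for i, _ in sorted(counts, key=lambda t: t[1])]
        lower = set(ranked[: len(ranked) // 2])
        upper = set(ranked[len(ranked) // 2 :])
        for subset in (split.train_ids, split.val_ids):
            assert set(subset) & lower and set(subset) & upper

    def test_zero_validation(self):
        split = dataprep.split_train_val([("a", 1), ("b", 2)], n_val=0)
        assert split.val_ids == [] and len(split.train_ids) == 2

    def test_validating_every_image_leaves_no_train(self):
        counts = [(i, i) for i in range(3)]
        split = dataprep.split_train_val(counts, n_val=3)
        assert sorted(split.val_ids) == [0, 1, 2]
        assert split.train_ids == []

    def test_single_validation_image_is_median_ranked(self):
        counts = list(zip("abcde", [50, 10, 30, 20, 40]))
        split = dataprep.split_train_val(counts, n_val=1)
        assert split.val_ids == ["c"]  # rank 2 of 0..4 by count

    def test_n_val_exceeding_images_raises(self):
        with pytest.raises(ValueError):
            dataprep.split_train_val([("a", 1)], n_val=2)
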