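import numpy as np
import pytest

from maskshaker import (
    CellPatch,
    LabelMask,
    MultichannelImage,
    PerturbationParams,
    ValidationError,
    apply_affine_patch,
    binary_opening,
    common_cell_ids,
    enforce_separation,
    extract_cell_patch,
    per_cell_iou,
    perturb_mask,
    qc_filter,
)
from maskshaker.perturb import _adjacent_pairs


def identity_params(**kw):
    kw.setdefault("opening_radius", 0)
    return PerturbationParams(**kw)


class TestExtractCellPatch:
    def test_square_cell_with_padding(self):
        arr = np.zeros((9, 9), dtype=np.int32)
        arr[3:6, 3:6] = 4
        patch = extract_cell_patch(LabelMask(arr), 4, pad=2)
        assert patch.shape == (7, 7)
        expected = np.zeros((7, 7), dtype=bool)
        expected[2:5, 2:5] = True
        np.testing.assert_array_equal(patch.pixels, expected)
        assert patch.offset == (1, 1)

    def test_round_trip_reproduces_pixel_set(self):
        arr = np.zeros((12, 12), dtype=np.int32)
        arr[2:5, 7:11] = 3
        patch = extract_cell_patch(LabelMask(arr), 3, pad=3)
        rows, cols = np.nonzero(patch.pixels)
        restored = set(zip((rows + patch.offset[0]).tolist(), (cols + patch.offset[1]).tolist()))
        assert restored == set(zip(*np.nonzero(arr == 3)))

    def test_border_cell_patch_extends_beyond_image(self):
        arr = np.zeros((5, 5), dtype=np.int32)
        arr[0:2, 0:2] = 1
        patch = extract_cell_patch(LabelMask(arr), 1, pad=1)
        assert patch.offset == (-1, -1)  # frame extends past the image
        out = np.zeros_like(arr)
        from maskshaker.perturb import _paste_patch

        _paste_patch(out, patch)
        np.testing.assert_array_equal(out, arr)  # write-back clips cleanly

    def test_absent_cell_raises(self):
        with pytest.raises(KeyError):
            extract_cell_patch(LabelMask(np.zeros((4, 4), dtype=np.int32)), 9)


class TestApplyAffine:
    def _square_patch(self, side=4, frame=16):
        arr = np.zeros((frame, frame), dtype=bool)
        lo = (frame - side) // 2
        arr[lo : lo + side, lo : lo + side] = True
        return CellPatch(arr, (0, 0), 1)

    def test_degenerate_intervals_are_identity(self, rng):
        patch = self._square_patch()
        out = apply_affine_patch(patch, identity_params(), rng)
        np.testing.assert_array_equal(out.pixels, patch.pixels)

    def test_fixed_translation_shifts_pixel_set(self, rng):
        patch = self._square_patch(side=4, frame=16)
        # translation of +0.5 bbox fractions = +2 px on a 4-px square, both axes
        params = identity_params(translate_frac=(0.5, 0.5))
        out = apply_affine_patch(patch, params, rng)
        np.testing.assert_array_equal(out.pixels, np.roll(patch.pixels, (2, 2), axis=(0, 1)))

    def test_scale_two_quadruples_area(self, rng):
        patch = self._square_patch(side=4, frame=24)
        params = identity_params(scale=(2.0, 2.0))
        out = apply_affine_patch(patch, params, rng)
        # nearest-neighbor rasterization of a doubled 4x4 square: 16 -> ~64 px
        assert abs(int(out.pixels.sum()) - 64) <= 17  # one-pixel boundary ring

    def test_empty_patch_rejected(self, rng):
        with pytest.raises(ValidationError):
            apply_affine_patch(CellPatch(np.zeros((4, 4), bool), (0, 0), 1), identity_params(), rng)


class TestBinaryOpening:
    def test_filled_square_unchanged(self):
        arr = np.zeros((9, 9), dtype=bool)
        arr[2:7, 2:7] = True
        out = binary_opening(CellPatch(arr, (0, 0), 1), radius=1)
        np.testing.assert_array_equal(out.pixels, arr)

    def test_isolated_pixel_removed(self):
        arr = np.zeros((5, 5), dtype=bool)
        arr[2, 2] = True
        out = binary_opening(CellPatch(arr, (0, 0), 1), radius=1)
        assert not out.pixels.any()

    def test_protrusion_removed_body_intact(self):
        arr = np.zeros((10, 12), dtype=bool)
        arr[2:8, 2:8] = True  # 6x6 body
        arr[4, 8:11] = True  # 1-px wide protrusion
        out = binary_opening(CellPatch(arr, (0, 0), 1), radius=1)
        body = np.zeros_like(arr)
        body[2:8, 2:8] = True
        np.testing.assert_array_equal(out.pixels, body)

    def test_radius_zero_is_identity(self):
        arr = np.zeros((3, 3), dtype=bool)
        arr[1, 1] = True
        out = binary_opening(CellPatch(arr, (0, 0), 1), radius=0)
        np.testing.assert_array_equal(out.pixels, arr)


class TestEnforceSeparation:
    def test_abutting_squares_get_border(self, rng):
        arr = np.zeros((8, 10), dtype=np.int32)
        arr[2:5, 2:5] = 1
        arr[2:5, 5:8] = 2  # directly abutting
        out = enforce_separation(LabelMask(arr), rng)
        assert len(_adjacent_pairs(out.pixels)) == 0
        # exactly one of the two cells lost pixels
        lost1 = (arr == 1).sum() - (out.pixels == 1).sum()
        lost2 = (arr == 2).sum() - (out.pixels == 2).sum()
        assert sorted([lost1 > 0, lost2 > 0]) == [False, True]

    def test_already_separated_unchanged(self, toy_mask, rng):
        out = enforce_separation(toy_mask, rng)
        np.testing.assert_array_equal(out.pixels, toy_mask.pixels)

    def test_three_mutually_touching_cells_terminate(self, rng):
        arr = np.zeros((8, 8), dtype=np.int32)
        arr[1:4, 1:4] = 1
        arr[1:4, 4:7] = 2
        arr[4:7, 1:7] = 3
        out = enforce_separation(LabelMask(arr), rng)
        assert len(_adjacent_pairs(out.pixels)) == 0
        assert set(np.unique(out.pixels)) <= {0, 1, 2, 3}


class TestPerturbMask:
    def test_identity_params_identity_map(self, toy_mask):
        out = perturb_mask(toy_mask, identity_params(seed=3))
        np.testing.assert_array_equal(out.pixels, toy_mask.pixels)

    def test_seeded_determinism(self, small_tissue):
        _, mask, _ = small_tissue
        params = PerturbationParams(
            translate_frac=(-0.2, 0.2), rotate_deg=(-10, 10), scale=(0.9, 1.1),
            shear_deg=(-5, 5), seed=13,
        )
        np.testing.assert_array_equal(
            perturb_mask(mask, params).pixels, perturb_mask(mask, params).pixels
        )

    def test_translation_only_matches_per_cell_oracle(self):
        # widely spaced cells; fixed +2px translation in rows on 4-px bbox
        arr = np.zeros((40, 40), dtype=np.int32)
        arr[4:8, 4:8] = 1
        arr[20:24, 25:29] = 2
        params = identity_params(translate_frac=(0.5, 0.5), seed=0)
        out = perturb_mask(LabelMask(arr), params)
        expected = np.roll(arr, (2, 2), axis=(0, 1))
        np.testing.assert_array_equal(out.pixels, expected)
        assert (per_cell_iou(LabelMask(arr), out) < 1).all()

    def test_output_labels_subset_of_input(self, small_tissue):
        _, mask, _ = small_tissue
        params = PerturbationParams(translate_frac=(-0.3, 0.3), seed=8)
        out = perturb_mask(mask, params)
        assert set(out.labels().tolist()) <= set(mask.labels().tolist())

    def test_separation_invariant_after_perturbation(self, small_tissue):
        _, mask, _ = small_tissue
        for seed in (1, 2):
            params = PerturbationParams(
                translate_frac=(-0.25, 0.25), rotate_deg=(-15, 15),
                scale=(0.9, 1.1), shear_deg=(-10, 10), seed=seed,
            )
            out = perturb_mask(mask, params)
            assert len(_adjacent_pairs(out.pixels)) == 0

    def test_iou_monotone_in_translation_strength(self, small_tissue):
        """Widening the translation interval must not raise median per-cell
        IoU (checked over 20 seeded replicates)."""
        _, mask, _ = small_tissue
        medians = []
        for t in (0.05, 0.15, 0.3):
            vals = []
            for seed in range(20):
                params = PerturbationParams(translate_frac=(-t, t), seed=seed)
                vals.append(per_cell_iou(mask, perturb_mask(mask, params)).median())
            medians.append(np.median(vals))
        assert medians[0] >= medians[1] >= medians[2]


class TestQCFilter:
    def _image_for(self, mask, nucleus_value=50.0):
        pix = np.zeros((2, *mask.shape), dtype=np.float32)
        pix[0] = 1.0
        pix[1][mask.pixels > 0] = nucleus_value
        return MultichannelImage(pix, ["CD3", "HOECHST"], "HOECHST")

    def test_small_cell_removed(self, toy_mask):
        arr = toy_mask.pixels.copy()
        arr[14, 14] = 3  # single-pixel cell
        mask = LabelMask(arr)
        out = qc_filter(mask, self._image_for(mask), min_area=10)
        assert 3 not in out.labels()
        assert {1, 2} <= set(out.labels().tolist())

    def test_nucleus_free_cell_removed(self, toy_mask):
        pix = np.zeros((2, *toy_mask.shape), dtype=np.float32)
        pix[1][toy_mask.pixels == 1] = 50.0  # cell 2 has no nucleus signal
        image = MultichannelImage(pix, ["CD3", "HOECHST"], "HOECHST")
        out = qc_filter(toy_mask, image, min_area=1)
        assert list(out.labels()) == [1]

    def test_permissive_thresholds_keep_synthetic_cells(self, small_tissue):
        image, mask, _ = small_tissue
        out = qc_filter(mask, image, min_area=1, min_nucleus_mean=0.0, max_area_factor=1e9)
        assert out.n_cells() == mask.n_cells()

    def test_oversized_merged_cell_removed(self, toy_mask):
        arr = toy_mask.pixels.copy()
        arr[0:16, 0:2] = 7  # blob 2x median area
        mask = LabelMask(arr)
        out = qc_filter(mask, self._image_for(mask), min_area=1, max_area_factor=1.5)
        assert 7 not in out.labels()


class TestCommonCellIds:
    def _mask_of(self, ids):
        arr = np.zeros((4, 4 * max(len(ids), 1)), dtype=np.int32)
        for i, cid in enumerate(sorted(ids)):
            arr[1:3, 4 * i : 4 * i + 2] = cid
        return LabelMask(arr)

    def test_intersection(self):
        masks = [self._mask_of(s) for s in ({1, 2, 3}, {2, 3}, {2, 3, 4})]
        assert common_cell_ids(masks) == {2, 3}

    def test_single_mask(self):
        assert common_cell_ids([self._mask_of({5, 9})]) == {5, 9}

    def test_disjoint(self):
        assert common_cell_ids([self._mask_of({1}), self._mask_of({2})]) == set()

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            common_cell_ids([])
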