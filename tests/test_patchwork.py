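"""Patch grids, extraction, augmentation and stitching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mfaunet import patchwork as pw


class TestPlanGrid:
    def test_exact_fit_yields_single_origin(self):
        grid = pw.plan_grid(128, 128, 128, 15)
        assert grid.origins == [(0, 0)]

    def test_drive_dimensions_give_930_origins(self):
        # 584x565 image, window 128, stride 15: 31 x 30 grid
        grid = pw.plan_grid(584, 565, 128, 15)
        assert len(grid) == 930

    def test_edge_completion_appends_final_origin(self):
        grid = pw.plan_grid(130, 128, 128, 15, edge_complete=True)
        assert grid.origins == [(0, 0), (2, 0)]

    def test_window_larger_than_image_raises(self):
        with pytest.raises(ValueError):
            pw.plan_grid(100, 100, 128, 15)

    @given(h=st.integers(16, 300), w=st.integers(16, 300),
           win=st.integers(4, 16), stride=st.integers(1, 20))
    @settings(max_examples=60, deadline=None)
    def test_origin_count_matches_closed_form(self, h, w, win, stride):
        grid = pw.plan_grid(h, w, win, stride)
        expect = ((h - win) // stride + 1) * ((w - win) // stride + 1)
        assert len(grid) == expect

    def test_edge_complete_grid_covers_every_pixel(self):
        grid = pw.plan_grid(70, 53, 16, 13, edge_complete=True)
        cover = np.zeros(grid.image_dims, dtype=int)
        for r, c in grid.origins:
            cover[r:r + 16, c:c + 16] += 1
        assert cover.min() >= 1


class TestOverlapPercent:
    @pytest.mark.parametrize("window,stride,expect", [
        (128, 128, 0.0),
        (128, 16, 87.5),
        (128, 15, 88.28125),
        (128, 200, 0.0),
    ])
    def test_values(self, window, stride, expect):
        assert pw.overlap_percent(window, stride) == expect


class TestExtractPatches:
    def test_constant_image(self):
        grid = pw.plan_grid(20, 20, 8, 6)
        pset = pw.extract_patches(np.full((20, 20), 0.3), None, grid)
        assert np.all(pset.images == 0.3)

    def test_single_origin_is_identity_crop(self, rng):
        img = rng.random((16, 16))
        grid = pw.plan_grid(16, 16, 16, 1)
        pset = pw.extract_patches(img, None, grid)
        np.testing.assert_array_equal(pset.images[0], img)

    def test_coordinate_bookkeeping(self):
        h, w, win = 30, 25, 7
        img = (np.arange(h)[:, None] * w + np.arange(w)).astype(float)
        grid = pw.plan_grid(h, w, win, 5)
        pset = pw.extract_patches(img, None, grid)
        for patch, (r, c) in zip(pset.images, grid.origins):
            for i in (0, 3, 6):
                for j in (0, 3, 6):
                    assert patch[i, j] == (r + i) * w + (c + j)

    def test_mask_cut_identically(self, rng):
        img = rng.random((20, 20))
        mask = (rng.random((20, 20)) > 0.5).astype(np.uint8)
        grid = pw.plan_grid(20, 20, 8, 4)
        pset = pw.extract_patches(img, mask, grid)
        for k, (r, c) in enumerate(grid.origins):
            np.testing.assert_array_equal(pset.masks[k], mask[r:r + 8, c:c + 8])

    def test_dim_mismatch_raises(self, rng):
        grid = pw.plan_grid(20, 20, 8, 4)
        with pytest.raises(ValueError):
            pw.extract_patches(rng.random((19, 20)), None, grid)


class TestAugment:
    def test_identity_params_are_noop(self, rng):
        img = rng.random((16, 16))
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        out_i, out_m = pw.apply_augment(img, mask, pw.AugmentParams())
        np.testing.assert_allclose(out_i, img)
        np.testing.assert_array_equal(out_m, mask)

    def test_double_hflip_is_involution(self, rng):
        img = rng.random((12, 12))
        p = pw.AugmentParams(hflip=True)
        once, _ = pw.apply_augment(img, None, p)
        twice, _ = pw.apply_augment(once, None, p)
        np.testing.assert_allclose(twice, img)

    def test_mask_stays_binary_under_random_transforms(self, rng):
        img = rng.random((16, 16))
        mask = (rng.random((16, 16)) > 0.7).astype(np.uint8)
        for seed in range(100):
            _, m = pw.augment_patch(img, mask, seed)
            assert set(np.unique(m)) <= {0, 1}

    def test_seed_determines_transform(self, rng):
        img = rng.random((16, 16))
        mask = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        a = pw.augment_patch(img, mask, 123)
        b = pw.augment_patch(img, mask, 123)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestStitch:
    def test_constant_predictions_stitch_to_constant(self):
        grid = pw.plan_grid(40, 30, 16, 9, edge_complete=True)
        patches = np.full((len(grid), 16, 16), 0.7, dtype=np.float32)
        np.testing.assert_allclose(pw.stitch(patches, grid), 0.7)

    def test_round_trip_is_exact(self, rng):
        prob = rng.random((50, 41)).astype(np.float32)
        grid = pw.plan_grid(50, 41, 16, 7, edge_complete=True)
        pset = pw.extract_patches(prob, None, grid)
        back = pw.stitch(pset.images, grid)
        assert np.array_equal(back, prob)

    def test_overlap_averages_disagreeing_patches(self):
        grid = pw.PatchGrid(window=4, stride=2, origins=[(0, 0), (0, 2)],
                            image_dims=(4, 6), edge_complete=True)
        p = np.stack([np.full((4, 4), 0.2), np.full((4, 4), 0.8)]).astype(np.float32)
        out = pw.stitch(p, grid)
        np.testing.assert_allclose(out[:, 2:4], 0.5)
        np.testing.assert_allclose(out[:, :2], 0.2)
        np.testing.assert_allclose(out[:, 4:], 0.8)

    def test_incomplete_coverage_raises(self):
        grid = pw.plan_grid(40, 40, 16, 15, edge_complete=False)
        patches = np.zeros((len(grid), 16, 16), dtype=np.float32)
        with pytest.raises(ValueError):
            pw.stitch(patches, grid)
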