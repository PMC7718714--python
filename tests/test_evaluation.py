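"""Dice metric, mask warping, stack evaluation and volume export."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

from roireg import (LumenMaskStack, PairRegistration, RigidTransform,
                    StackRegistrationResult, dice, evaluate_stack,
                    export_volume, warp_mask_stack)


def disc_mask(shape, cx, cy, r):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return np.hypot(xx - cx, yy - cy) < r


def identity_result(n, shape):
    ident = RigidTransform(0, 0, 0, 0, ((shape[1] - 1) / 2, (shape[0] - 1) / 2))
    return StackRegistrationResult(
        [PairRegistration(i, ident, ident) for i in range(n)])


class TestDice:
    def test_identical_nonzero_masks_give_one(self):
        m = disc_mask((32, 32), 16, 16, 6)
        assert dice(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = disc_mask((32, 32), 8, 8, 4)
        b = disc_mask((32, 32), 24, 24, 4)
        assert dice(a, b) == 0.0

    def test_half_overlap_formula(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, :4] = True          # |A| = 4
        b[0, 2:] = True
        b[1, :2] = True          # |B| = 4, |A∩B| = 2
        assert dice(a, b) == 0.5

    def test_both_empty_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(dice(np.zeros((4, 4), bool), np.zeros((4, 4), bool)))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_random_masks_against_set_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16)) > 0.5
        b = rng.random((16, 16)) > 0.5
        if not (a.any() or b.any()):
            return
        # oracle: explicit pixel-coordinate sets
        sa = {(i, j) for i in range(16) for j in range(16) if a[i, j]}
        sb = {(i, j) for i in range(16) for j in range(16) if b[i, j]}
        expected = 2 * len(sa & sb) / (len(sa) + len(sb))
        d = dice(a, b)
        assert d == pytest.approx(expected, abs=1e-12)
        assert d == dice(b, a)
        assert 0.0 <= d <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.ones((3, 3), bool), np.ones((4, 4), bool))


class TestWarpMaskStack:
    def test_identity_transforms_leave_masks_unchanged(self):
        masks = LumenMaskStack([disc_mask((64, 64), 30, 30, 8)] * 3)
        out = warp_mask_stack(masks, identity_result(3, (64, 64)))
        for m, o in zip(masks.masks, out.masks):
            assert np.array_equal(m, o)

    def test_integer_translation_is_exact_shift(self):
        m = disc_mask((64, 64), 30, 30, 8)
        t = RigidTransform(0.0, 5.0, -3.0, 0, (31.5, 31.5))
        ident = RigidTransform(0, 0, 0, 0, (31.5, 31.5))
        res = StackRegistrationResult([PairRegistration(0, ident, t)])
        out = warp_mask_stack(LumenMaskStack([m]), res)
        assert np.array_equal(out.masks[0], disc_mask((64, 64), 35, 27, 8))
        assert out.masks[0].sum() == m.sum()

    def test_rotated_disc_preserves_area_within_tolerance(self):
        m = disc_mask((64, 64), 31.5, 31.5, 12)
        t = RigidTransform(30.0, 0.0, 0.0, 0, (31.5, 31.5))
        ident = RigidTransform(0, 0, 0, 0, (31.5, 31.5))
        res = StackRegistrationResult([PairRegistration(0, ident, t)])
        out = warp_mask_stack(LumenMaskStack([m]), res)
        assert abs(int(out.masks[0].sum()) - int(m.sum())) <= 0.03 * m.sum()

    def test_count_mismatch_rejected(self):
        masks = LumenMaskStack([disc_mask((16, 16), 8, 8, 3)] * 2)
        with pytest.raises(ValueError):
            warp_mask_stack(masks, identity_result(3, (16, 16)))


class TestEvaluateStack:
    def test_identical_masks_mean_one_std_zero(self):
        masks = LumenMaskStack([disc_mask((32, 32), 16, 16, 6)] * 4)
        rep = evaluate_stack(masks)
        assert rep.mean == 1.0 and rep.std == 0.0
        assert len(rep.pairwise) == 3

    def test_alternating_disjoint_masks_mean_zero(self):
        a = disc_mask((32, 32), 8, 8, 4)
        b = disc_mask((32, 32), 24, 24, 4)
        rep = evaluate_stack(LumenMaskStack([a, b, a, b]))
        assert rep.mean == 0.0

    def test_empty_pair_recorded_nan_and_excluded(self):
        a = disc_mask((32, 32), 16, 16, 6)
        empty = np.zeros((32, 32), bool)
        with pytest.warns(RuntimeWarning):
            rep = evaluate_stack(LumenMaskStack([empty, empty, a, a]))
        assert np.isnan(rep.pairwise[0]["dsc"])
        assert rep.mean == pytest.approx((0.0 + 1.0) / 2)

    def test_mean_std_recomputable_from_pairwise(self):
        rng = np.random.default_rng(0)
        masks = LumenMaskStack([rng.random((16, 16)) > 0.4 for _ in range(5)])
        rep = evaluate_stack(masks)
        vals = [p["dsc"] for p in rep.pairwise]
        assert rep.mean == pytest.approx(np.mean(vals), abs=1e-12)
        assert rep.std == pytest.approx(np.std(vals), abs=1e-12)

    def test_registration_improves_dice_on_shifted_discs(self):
        # misalignment larger than radius/4 → correcting it must help
        shape = (64, 64)
        masks = [disc_mask(shape, 32, 32, 10), disc_mask(shape, 44, 32, 10)]
        before = evaluate_stack(LumenMaskStack(masks)).mean
        ident = RigidTransform(0, 0, 0, 0, (31.5, 31.5))
        fix = RigidTransform(0.0, -12.0, 0.0, 0, (31.5, 31.5))
        res = StackRegistrationResult([PairRegistration(0, ident, ident),
                                       PairRegistration(1, ident, fix)])
        after = evaluate_stack(warp_mask_stack(LumenMaskStack(masks), res)).mean
        assert after > before


class TestExportVolume:
    def test_pages_roundtrip_bitwise(self, tmp_path):
        rng = np.random.default_rng(1)
        slices = [rng.integers(0, 255, (32, 32)).astype(np.uint8) for _ in range(5)]
        out = tmp_path / "vol.tif"
        export_volume(slices, out)
        vol = tifffile.imread(str(out))
        assert vol.shape == (5, 32, 32)
        for z in range(5):
            assert np.array_equal(vol[z], slices[z])

    def test_mask_stack_is_binary_valued(self, tmp_path):
        masks = [disc_mask((16, 16), 8, 8, 4)] * 3
        out = tmp_path / "masks.tif"
        export_volume(masks, out)
        vol = tifffile.imread(str(out))
        assert set(np.unique(vol)) <= {0, 255}

    def test_empty_stack_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_volume([], tmp_path / "x.tif")
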