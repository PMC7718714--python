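"""Multi-scale attention ROI registration: matching, candidates, selection."""

import itertools
import math

import numpy as np
import pytest

from roireg import (AttentionParams, KeypointMatch, ROIBox, RigidTransform,
                    build_pyramid, detect_and_match, enumerate_rigid_candidates,
                    extract_roi_at_level, register_roi_level, register_roi_pair,
                    roi_ssd, select_strong_matches, warp_image)
from roireg.attention import _candidate_ssd


def make_matches(n, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(10, 100, size=(n, 4))
    d = np.sort(rng.random(n))
    return [KeypointMatch((p[0], p[1]), (p[2], p[3]), float(dd))
            for p, dd in zip(pts, d)]


class TestExtractROI:
    def test_center_rescaling_and_clamping(self):
        roi0 = ROIBox(800.0, 600.0, 256, 256, 0)
        roi2 = extract_roi_at_level(roi0, 2, (256, 256))
        assert (roi2.center_x, roi2.center_y) == (200.0, 150.0)
        x0, y0, w, h = roi2.bounds((256, 256))
        assert 0 <= x0 and x0 + w <= 256 and 0 <= y0 and y0 + h <= 256
        assert (w, h) == (256, 256)  # attention window spans the coarse image

    def test_level_zero_is_identity(self):
        roi0 = ROIBox(300.0, 200.0, 128, 128, 0)
        out = extract_roi_at_level(roi0, 0, (512, 512))
        assert out == roi0

    def test_oversized_window_degenerates_to_whole_image(self):
        roi0 = ROIBox(512.0, 512.0, 300, 300, 0)
        roi3 = extract_roi_at_level(roi0, 3, (128, 128))
        assert roi3.bounds((128, 128)) == (0, 0, 128, 128)

    def test_attention_ratio_nondecreasing_with_level(self):
        # ROI-to-image area ratio grows (or saturates) as levels coarsen
        roi0 = ROIBox(300.0, 260.0, 128, 128, 0)
        ratios = []
        for r in range(4):
            shape = (512 // 2**r, 512 // 2**r)
            _, _, w, h = extract_roi_at_level(roi0, r, shape).bounds(shape)
            ratios.append((w * h) / (shape[0] * shape[1]))
        assert all(b >= a for a, b in zip(ratios, ratios[1:]))

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError):
            extract_roi_at_level(ROIBox(-5.0, 10.0, 32, 32, 0), 0, (64, 64))


class TestSelectStrongMatches:
    def test_twelve_in_eight_out_smallest_distances(self):
        matches = make_matches(12)
        out = select_strong_matches(matches, 8)
        assert len(out) == 8
        assert [m.descriptor_distance for m in out] == sorted(
            m.descriptor_distance for m in matches)[:8]

    def test_fewer_than_n_returns_all(self):
        assert len(select_strong_matches(make_matches(5), 8)) == 5

    def test_empty_in_empty_out(self):
        assert select_strong_matches([], 8) == []

    def test_rejects_pool_too_small_for_rigid_fit(self):
        with pytest.raises(ValueError):
            select_strong_matches(make_matches(5), 2)


class TestEnumerateCandidates:
    @pytest.mark.parametrize("n,expected", [(3, 1), (5, 10), (8, 56)])
    def test_candidate_count_is_n_choose_3(self, n, expected):
        cands = enumerate_rigid_candidates(make_matches(n))
        assert len(cands) == expected
        assert expected == math.comb(n, 3)

    def test_fewer_than_three_matches_yields_empty(self):
        assert enumerate_rigid_candidates(make_matches(2)) == []

    def test_each_candidate_agrees_with_analytic_triplet_solver(self):
        # oracle: closed-form angle from paired centered vectors (no SVD)
        matches = make_matches(5, seed=3)
        cands = enumerate_rigid_candidates(matches)
        for trip, cand in zip(itertools.combinations(matches, 3), cands):
            mov = np.array([m.p_moving for m in trip])
            fix = np.array([m.p_fixed for m in trip])
            a, b = mov - mov.mean(axis=0), fix - fix.mean(axis=0)
            theta = math.atan2(float(np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])),
                               float(np.sum(a * b)))
            assert cand.theta_deg == pytest.approx(math.degrees(theta), abs=1e-6)

    def test_collinear_triplet_flagged_identity_count_preserved(self):
        matches = [KeypointMatch((float(i), float(i)), (float(i) + 2, float(i)), 0.1 * i)
                   for i in range(4)]  # all fixed points on y=x
        cands = enumerate_rigid_candidates(matches)
        assert len(cands) == 4
        assert all(c.note == "degenerate_triplet" and c.is_identity for c in cands)


class TestRoiSSD:
    def test_identical_images_zero(self):
        img = np.random.default_rng(0).random((32, 32))
        roi = ROIBox(16.0, 16.0, 16, 16, 0)
        assert roi_ssd(img, img, roi) == 0.0

    def test_unit_difference_over_10x10_roi_is_100(self):
        roi = ROIBox(16.0, 16.0, 10, 10, 0)
        assert roi_ssd(np.zeros((32, 32)), np.ones((32, 32)), roi) == 100.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        a, b = rng.random((32, 32)), rng.random((32, 32))
        roi = ROIBox(15.0, 17.0, 20, 12, 0)
        x0, y0, w, h = roi.bounds((32, 32))
        oracle = 0.0
        for y in range(y0, y0 + h):
            for x in range(x0, x0 + w):
                oracle += (a[y, x] - b[y, x]) ** 2
        assert roi_ssd(a, b, roi) == pytest.approx(oracle, rel=1e-12)

    def test_fast_candidate_ssd_equals_full_warp_path(self):
        rng = np.random.default_rng(2)
        from scipy import ndimage as ndi

        img = ndi.gaussian_filter(rng.random((64, 64)) * 100, 1.0)
        mov = ndi.gaussian_filter(rng.random((64, 64)) * 100, 1.0)
        roi = ROIBox(32.0, 32.0, 24, 24, 0)
        t = RigidTransform(7.0, 3.0, -2.0, 0, (31.5, 31.5))
        fast = _candidate_ssd(img, mov, roi, t, fill=50.0)
        slow = roi_ssd(img, warp_image(mov, t, fill=50.0), roi)
        assert fast == pytest.approx(slow, rel=1e-9)


class TestDetectAndMatch:
    def test_identical_images_match_in_place(self, textured_image):
        roi = ROIBox(128.0, 128.0, 128, 128, 0)
        matches = detect_and_match(textured_image, textured_image, roi)
        assert len(matches) > 10
        for m in matches:
            assert m.p_fixed == m.p_moving
            assert m.descriptor_distance == 0.0

    def test_matches_sorted_ascending_and_inside_roi(self, textured_image):
        roi = ROIBox(128.0, 128.0, 160, 160, 0)
        shifted = np.roll(textured_image, (4, -3), axis=(0, 1))
        matches = detect_and_match(textured_image, shifted, roi)
        d = [m.descriptor_distance for m in matches]
        assert d == sorted(d)
        shape = textured_image.shape
        for m in matches:
            assert roi.contains(*m.p_fixed, shape)
            assert roi.contains(*m.p_moving, shape)

    def test_zero_spatial_weight_reduces_to_raw_descriptor_matching(
            self, textured_image):
        # oracle: dense raw-descriptor distance matrix + mutual NN extraction
        from scipy.spatial.distance import cdist
        from skimage.feature import SIFT

        roi = ROIBox(128.0, 128.0, 128, 128, 0)
        shifted = np.roll(textured_image, (6, 0), axis=(0, 1))
        matches = detect_and_match(textured_image, shifted, roi,
                                   spatial_weight=0.0)

        x0, y0, w, h = roi.bounds(textured_image.shape)
        crops = [textured_image[y0:y0 + h, x0:x0 + w], shifted[y0:y0 + h, x0:x0 + w]]
        kps, descs = [], []
        for c in crops:
            det = SIFT(n_scales=10)
            det.detect_and_extract(c)
            kps.append(det.keypoints)
            descs.append(det.descriptors.astype(float))
        d = cdist(descs[0], descs[1])
        expected = set()
        for i in range(d.shape[0]):
            j = int(d[i].argmin())
            if int(d[:, j].argmin()) == i:
                expected.add((
                    (float(kps[0][i, 1] + x0), float(kps[0][i, 0] + y0)),
                    (float(kps[1][j, 1] + x0), float(kps[1][j, 0] + y0)),
                    round(float(d[i, j]), 6),
                ))
        got = {(m.p_fixed, m.p_moving, round(m.descriptor_distance, 6))
               for m in matches}
        assert got == expected

    def test_translated_pair_matches_correspond(self, textured_image):
        roi = ROIBox(128.0, 128.0, 128, 128, 0)
        shifted = np.roll(textured_image, (0, 6), axis=(0, 1))  # +6 px in x
        matches = detect_and_match(textured_image, shifted, roi)
        ok = sum(1 for m in matches
                 if abs(m.p_moving[0] - m.p_fixed[0] - 6) < 1.5
                 and abs(m.p_moving[1] - m.p_fixed[1]) < 1.5)
        assert ok / len(matches) >= 0.8

    def test_featureless_images_give_no_matches(self):
        roi = ROIBox(32.0, 32.0, 32, 32, 0)
        assert detect_and_match(np.full((64, 64), 5.0), np.full((64, 64), 5.0),
                                roi) == []


class TestRegisterRoiLevel:
    def test_identity_on_identical_images(self, textured_image):
        roi = ROIBox(128.0, 128.0, 96, 96, 0)
        rec = register_roi_level(textured_image, textured_image, roi)
        assert rec.chosen_transform.is_identity
        assert rec.best_ssd == 0.0

    def test_constant_roi_returns_flagged_identity(self):
        roi = ROIBox(32.0, 32.0, 32, 32, 0)
        rec = register_roi_level(np.full((64, 64), 9.0), np.full((64, 64), 9.0), roi)
        assert rec.chosen_transform.is_identity
        assert "too_few_matches" in rec.flags
        assert rec.candidate_count == 0

    def test_recovers_small_rigid_perturbation(self, textured_image):
        roi = ROIBox(128.0, 128.0, 128, 128, 0)
        true = RigidTransform(5.0, 4.0, -6.0, 0, (127.5, 127.5))
        fill = float(np.median(textured_image))
        moving = warp_image(textured_image, true.inverse(), fill=fill)
        rec = register_roi_level(textured_image, moving, roi,
                                 AttentionParams(fill=fill))
        t = rec.chosen_transform
        assert t.theta_deg == pytest.approx(5.0, abs=0.5)
        assert t.dx == pytest.approx(4.0, abs=1.0)
        assert t.dy == pytest.approx(-6.0, abs=1.0)

    def test_chosen_ssd_never_worse_than_identity(self, textured_image):
        roi = ROIBox(128.0, 128.0, 96, 96, 0)
        rng = np.random.default_rng(3)
        moving = np.roll(textured_image, (3, -2), axis=(0, 1)) + rng.normal(
            0, 2, textured_image.shape)
        rec = register_roi_level(textured_image, moving, roi)
        ssd_identity = roi_ssd(textured_image, moving, roi)
        assert rec.best_ssd <= ssd_identity + 1e-9
        assert rec.candidate_count <= 56


class TestRegisterRoiPair:
    def test_identical_pyramids_give_identity(self, textured_image):
        pyr = build_pyramid(textured_image, 3)
        roi0 = ROIBox(128.0, 128.0, 96, 96, 0)
        f, recs = register_roi_pair(pyr, pyr, roi0, 3)
        assert np.linalg.norm(f.as_matrix() - np.eye(3)) < 1e-9
        assert len(recs) == 3

    def test_single_level_equals_level_registration(self, textured_image):
        pyr = build_pyramid(textured_image, 1)
        rng = np.random.default_rng(4)
        moving = build_pyramid(
            np.roll(textured_image, (2, 5), axis=(0, 1)), 1)
        roi0 = ROIBox(128.0, 128.0, 128, 128, 0)
        f, recs = register_roi_pair(pyr, moving, roi0, 1)
        lone = register_roi_level(textured_image, moving[0].pixels, roi0)
        assert np.allclose(f.as_matrix(), lone.chosen_transform.as_matrix(),
                           atol=1e-9)

    def test_composition_matches_level_product(self, textured_image):
        true = RigidTransform(4.0, 10.0, -7.0, 0, (127.5, 127.5))
        fill = float(np.median(textured_image))
        moving = warp_image(textured_image, true.inverse(), fill=fill)
        fixed_pyr = build_pyramid(textured_image, 3)
        moving_pyr = build_pyramid(moving, 3)
        roi0 = ROIBox(128.0, 128.0, 128, 128, 0)
        f, recs = register_roi_pair(fixed_pyr, moving_pyr, roi0, 3,
                                    AttentionParams(fill=fill))
        # F* is the ordered product of the per-level transforms at level 0
        m = np.eye(3)
        for rec in recs:  # recorded coarse→fine; F* = F_0 F_1 ... F_k
            m = rec.chosen_transform.rescale_to_level(0).as_matrix() @ m
        assert np.linalg.norm(f.as_matrix() - m) < 1e-9

    def test_too_shallow_pyramid_rejected(self, textured_image):
        pyr = build_pyramid(textured_image, 2)
        with pytest.raises(ValueError, match="levels"):
            register_roi_pair(pyr, pyr, ROIBox(128.0, 128.0, 64, 64, 0), 4)
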