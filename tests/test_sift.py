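"""Feature extraction: scale space, DoG extrema, refinement, orientation
assignment, descriptors."""

import math

import numpy as np
import pytest
from numpy.testing import assert_allclose, assert_array_equal

from beaverid.imaging import resize_working
from beaverid.matching import MatchConfig, match_images
from beaverid.sift import (DoGPyramid, SIFTConfig, assign_orientations,
                           build_dog, build_scale_space, compute_descriptor,
                           detect_extrema, extract_features, gradient_at,
                           passes_edge_test, refine_candidate)
from beaverid.synthetic import make_pattern

from conftest import small_spec

CFG = SIFTConfig()


def brute_force_extrema(dog: DoGPyramid):
    """Independent 26-neighbour scan: triple loop over every interior pixel
    of every interior DoG level."""
    found = set()
    for o, levels in enumerate(dog.octaves):
        L = len(levels)
        h, w = levels[0].shape
        for l in range(1, L - 1):
            for y in range(1, h - 1):
                for x in range(1, w - 1):
                    v = levels[l][y, x]
                    neigh = []
                    for dl in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                if dl == dy == dx == 0:
                                    continue
                                neigh.append(levels[l + dl][y + dy, x + dx])
                    neigh = np.array(neigh)
                    if np.all(v > neigh) or np.all(v < neigh):
                        found.add((o, l, x, y))
    return found


class TestScaleSpace:
    def test_shape_and_level_counts(self, pattern_small):
        pyr = build_scale_space(pattern_small, CFG)
        assert pyr.n_octaves == 4
        assert all(len(o) == 5 for o in pyr.octaves)
        # octave bases halve in resolution
        for o in range(1, 4):
            prev = pyr.octaves[o - 1][0].shape
            assert pyr.octaves[o][0].shape == ((prev[0] + 1) // 2,
                                               (prev[1] + 1) // 2)

    def test_sigma_ladder(self, pattern_small):
        pyr = build_scale_space(pattern_small, CFG)
        for o, sig in enumerate(pyr.sigmas):
            for j, s in enumerate(sig):
                assert s == pytest.approx(1.6 * math.sqrt(2) ** j * 2 ** o)

    def test_constant_image_stays_constant(self):
        pyr = build_scale_space(np.full((64, 64), 0.7), CFG)
        for levels in pyr.octaves:
            for L in levels:
                assert_allclose(L, 0.7, atol=1e-12)

    def test_impulse_matches_direct_gaussian_kernel(self):
        """First level of octave 0 on an impulse equals a directly evaluated
        (sampled, normalized) 2-D Gaussian of sigma 1.6."""
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        pyr = build_scale_space(img, CFG)
        level0 = pyr.octaves[0][0]

        sigma = 1.6
        r = int(4.0 * sigma + 0.5)  # same truncation as the implementation
        ax = np.arange(-r, r + 1)
        k1 = np.exp(-ax ** 2 / (2 * sigma ** 2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        assert_allclose(level0[32 - r:32 + r + 1, 32 - r:32 + r + 1],
                        kernel, atol=1e-12)

    def test_small_image_reduces_octaves(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            pyr = build_scale_space(np.random.default_rng(0).uniform(
                0, 1, size=(40, 40)), CFG)
        assert pyr.n_octaves < 4
        assert any("octaves" in r.message for r in caplog.records)


class TestDoG:
    def test_counts_and_definition(self, pattern_small):
        pyr = build_scale_space(pattern_small, CFG)
        dog = build_dog(pyr)
        assert all(len(o) == 4 for o in dog.octaves)
        for o in range(4):
            for j in range(4):
                assert_array_equal(
                    dog.octaves[o][j],
                    pyr.octaves[o][j + 1] - pyr.octaves[o][j])

    def test_constant_image_zero_dog(self):
        dog = build_dog(build_scale_space(np.full((64, 64), 0.3), CFG))
        for levels in dog.octaves:
            for d in levels:
                assert_allclose(d, 0.0, atol=1e-12)


class TestDetectExtrema:
    def test_constant_image_no_candidates(self):
        dog = build_dog(build_scale_space(np.full((64, 64), 0.5), CFG))
        assert detect_extrema(dog) == []

    def test_bright_blob_produces_extremum_at_its_location(self):
        """A bright blob of finite width has a preferred scale and must
        appear as a scale-space extremum at its location.  (A literal 1-px
        impulse does not: its DoG response is monotone across scale.)"""
        yy, xx = np.mgrid[0:64, 0:64]
        img = 0.2 + 0.8 * np.exp(-((xx - 35) ** 2 + (yy - 31) ** 2)
                                 / (2 * 3.0 ** 2))
        dog = build_dog(build_scale_space(img, CFG))
        cands = detect_extrema(dog)
        assert any(abs(x * 2 ** o - 35) <= 2 and abs(y * 2 ** o - 31) <= 2
                   for o, l, x, y in cands)
        assert set(cands) == brute_force_extrema(dog)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, size=(64, 64))
        dog = build_dog(build_scale_space(img, CFG))
        assert set(detect_extrema(dog)) == brute_force_extrema(dog)

    def test_plateau_produces_no_candidate(self):
        # a flat-topped blob: ties in the 26-neighbourhood are excluded
        img = np.full((64, 64), 0.1)
        img[30:34, 30:34] = 0.9
        dog = build_dog(build_scale_space(img, CFG))
        cands = set(detect_extrema(dog))
        assert cands == brute_force_extrema(dog)


class TestRefineCandidate:
    def _dog_with_peak(self, peak):
        """DoG pyramid holding one quadratic bump of the given height."""
        levels = []
        yy, xx = np.mgrid[0:16, 0:16]
        for l in range(4):
            amp = peak * (1.0 - 0.2 * abs(l - 1))
            levels.append(amp * np.exp(-((xx - 8) ** 2 + (yy - 8) ** 2) / 4.0))
        return DoGPyramid(octaves=[levels], config=CFG)

    def test_low_contrast_rejected(self):
        dog = self._dog_with_peak(0.01)
        kp, reason = refine_candidate((0, 1, 8, 8), dog, CFG)
        assert kp is None and reason == "low_contrast"

    def test_strong_peak_kept_with_subpixel_position(self):
        dog = self._dog_with_peak(0.5)
        kp, reason = refine_candidate((0, 1, 8, 8), dog, CFG)
        assert reason is None
        assert kp.x == pytest.approx(8.0, abs=0.1)
        assert kp.y == pytest.approx(8.0, abs=0.1)
        assert abs(kp.response) >= CFG.contrast_threshold

    def test_edge_arithmetic_kept(self):
        # tr^2/det = (10+10)^2 / 100 = 4 < 12.1 = 11^2/10
        assert passes_edge_test(10.0, 10.0, 0.0, edge_r=10.0)

    def test_edge_arithmetic_rejected(self):
        # tr^2/det = 101^2/100 = 102.01 >= 12.1
        assert not passes_edge_test(100.0, 1.0, 0.0, edge_r=10.0)

    def test_negative_determinant_rejected(self):
        assert not passes_edge_test(5.0, -5.0, 0.0, edge_r=10.0)

    def test_elongated_ridge_rejected_as_edge(self):
        # a long straight dark line is an edge response, not a corner
        img = np.full((64, 64), 0.8)
        img[30:32, :] = 0.0
        dog = build_dog(build_scale_space(img, CFG))
        reasons = {refine_candidate(c, dog, CFG)[1]
                   for c in detect_extrema(dog)
                   if c[0] == 0 and 20 < c[3] < 42 and 10 < c[2] < 54}
        assert "edge" in reasons or not reasons


class TestGradientAt:
    def test_three_four_five_triangle(self):
        L = np.zeros((3, 3))
        L[1, 2], L[1, 0] = 2.0, -1.0   # dx = 3
        L[2, 1], L[0, 1] = 3.0, -1.0   # dy = 4
        m, theta = gradient_at(L, 1, 1)
        assert m == pytest.approx(5.0)
        assert theta == pytest.approx(math.degrees(math.atan2(4, 3)), abs=1e-9)
        assert theta == pytest.approx(53.130, abs=1e-3)

    def test_flat_neighbourhood_zero_by_convention(self):
        m, theta = gradient_at(np.full((3, 3), 0.5), 1, 1)
        assert m == 0.0 and theta == 0.0

    def test_negative_dx_points_at_180(self):
        L = np.zeros((3, 3))
        L[1, 0] = 1.0                  # dx = -1, dy = 0
        m, theta = gradient_at(L, 1, 1)
        assert m == pytest.approx(1.0)
        assert theta == pytest.approx(180.0)

    def test_border_pixel_rejected(self):
        with pytest.raises(ValueError):
            gradient_at(np.zeros((5, 5)), 0, 2)


def _make_pyramid_from(patch):
    """Pyramid stub exposing a ready-made level for orientation tests."""
    from beaverid.sift import GaussianPyramid
    return GaussianPyramid(octaves=[[patch] * 5],
                           sigmas=[[1.6 * math.sqrt(2) ** j for j in range(5)]],
                           config=CFG)


def _center_kp(patch):
    from beaverid.sift import Keypoint
    h, w = patch.shape
    return Keypoint(x=(w - 1) / 2, y=(h - 1) / 2, octave=0, level=1,
                    sigma=1.6, response=0.1)


class TestAssignOrientations:
    def test_horizontal_ramp_single_peak_at_zero(self):
        xx = np.tile(np.linspace(0, 1, 33), (33, 1))
        out = assign_orientations(_center_kp(xx), _make_pyramid_from(xx), CFG)
        assert len(out) == 1
        angle = out[0].orientation
        assert min(angle, 360 - angle) <= 5.0

    def test_two_equal_energy_populations_two_keypoints(self):
        """A V-shaped ramp |x - xc| carries two exactly equal gradient
        populations (+x and -x): two histogram peaks above the 80% rule ->
        two oriented keypoints."""
        n = 33
        xx = np.tile(np.arange(n, dtype=float), (n, 1))
        patch = np.abs(xx - (n - 1) / 2) / n

        out = assign_orientations(_center_kp(patch),
                                  _make_pyramid_from(patch), CFG)
        angles = sorted(kp.orientation % 360 for kp in out)
        assert len(out) == 2
        assert min(angles[0], 360 - angles[0]) <= 10
        assert abs(angles[1] - 180) <= 10

        # independent oracle: direct summation histogram over the window
        hist = np.zeros(36)
        kp = _center_kp(patch)
        radius = int(round(3 * 1.5 * 1.6))
        for y in range(1, n - 1):
            for x in range(1, n - 1):
                r2 = (x - kp.x) ** 2 + (y - kp.y) ** 2
                if r2 > radius ** 2:
                    continue
                dx = patch[y, x + 1] - patch[y, x - 1]
                dy = patch[y + 1, x] - patch[y - 1, x]
                m = math.hypot(dx, dy)
                if m == 0:
                    continue
                theta = math.degrees(math.atan2(dy, dx)) % 360
                w = m * math.exp(-r2 / (2 * (1.5 * 1.6) ** 2))
                hist[int(round(theta / 10)) % 36] += w
        top2 = set(np.argsort(hist)[-2:])
        assert top2 == {0, 18}
        assert hist[0] == pytest.approx(hist[18], rel=1e-9)

    def test_constant_patch_discarded(self):
        patch = np.full((33, 33), 0.5)
        out = assign_orientations(_center_kp(patch),
                                  _make_pyramid_from(patch), CFG)
        assert out == []


class TestDescriptor:
    def test_length_and_norm(self, features_small):
        assert features_small.descriptors.shape[1] == 128
        norms = np.linalg.norm(features_small.descriptors, axis=1)
        assert_allclose(norms, 1.0, atol=1e-6)
        assert (features_small.descriptors >= 0).all()

    def test_single_keypoint_path_matches_batch(self, pattern_small,
                                                features_small):
        """compute_descriptor on one keypoint reproduces the batched row."""
        pyr = build_scale_space(pattern_small, CFG)
        for i in (0, len(features_small) // 2, len(features_small) - 1):
            kp = features_small.keypoints[i]
            d = compute_descriptor(kp, pyr, CFG)
            assert_allclose(d, features_small.descriptors[i], atol=1e-12)

    def test_rotated_copy_descriptor_distances(self, pattern_small):
        """Keypoints matched between an image and its 90-degree rotation
        have close descriptors; unrelated keypoint pairs do not."""
        a = extract_features(pattern_small, CFG, image_id="a")
        b = extract_features(np.rot90(pattern_small).copy(), CFG,
                             image_id="b")
        res = match_images(a, b, MatchConfig())
        assert res.n_matches >= 10
        matched = np.array([d for _, _, d in res.pairs])
        assert matched.mean() < 0.5

        rng = np.random.default_rng(0)
        ia = rng.integers(0, len(a), 200)
        ib = rng.integers(0, len(b), 200)
        rand_d = np.linalg.norm(a.descriptors[ia] - b.descriptors[ib], axis=1)
        assert rand_d.mean() > 0.8
        assert rand_d.mean() > 2.0 * matched.mean()


class TestExtractFeatures:
    def test_constant_image_empty_featureset(self):
        fs = extract_features(np.full((64, 64), 0.5), CFG, image_id="c")
        assert len(fs) == 0
        assert fs.descriptors.shape == (0, 128)

    def test_pattern_yields_many_keypoints(self, features_small):
        assert len(features_small) >= 50

    def test_deterministic(self, pattern_small):
        a = extract_features(pattern_small, CFG)
        b = extract_features(pattern_small, CFG)
        assert [k for k in a.keypoints] == [k for k in b.keypoints]
        assert_array_equal(a.descriptors, b.descriptors)

    def test_keypoints_inside_image(self, pattern_small, features_small):
        h, w = pattern_small.shape
        for kp in features_small.keypoints:
            assert 0 <= kp.x < w and 0 <= kp.y < h
            assert abs(kp.response) >= CFG.contrast_threshold
            assert 0 <= kp.orientation < 360


class TestScaleAndRotationBehaviour:
    @pytest.mark.parametrize("seed", range(5))
    def test_scale_covariance_under_downsampling(self, seed):
        """At least 30% of keypoints of a 2x-downsampled pattern have a
        counterpart in the full-size pattern within 2 px after scaling."""
        pat = make_pattern(small_spec(100 + seed))
        small = resize_working(pat, pat.shape[1] // 2, pat.shape[0] // 2)
        f_big = extract_features(pat, CFG)
        f_small = extract_features(small, CFG)
        assert len(f_small) > 0
        big_xy = np.array([[k.x, k.y] for k in f_big.keypoints])
        hits = 0
        for k in f_small.keypoints:
            d = np.hypot(big_xy[:, 0] - 2 * k.x, big_xy[:, 1] - 2 * k.y)
            if d.min() <= 2.0:
                hits += 1
        assert hits / len(f_small) >= 0.30
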