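"""Transform fitting (vs a normal-equations oracle), warping, standardization."""

import numpy as np
import pytest

from microspot import Aberration, SceneSpec, reference_centroids, render
from microspot.config import AnalysisConfig
from microspot.detection import find_blobs, match_anchors, threshold_mask
from microspot.errors import GeometryError
from microspot.geometry import (
    AffineTransform,
    QuadraticTransform,
    crop_to_spots,
    estimate_affine,
    fit_quadratic,
    standardize,
    standardized_shape,
    warp_image,
)
from microspot.imaging import to_luminance


def affine_oracle(src, dst):
    """Independent normal-equations solution for the affine fit."""
    X = np.column_stack([src[:, 0], src[:, 1], np.ones(len(src))])
    coef_x = np.linalg.solve(X.T @ X, X.T @ dst[:, 0])
    coef_y = np.linalg.solve(X.T @ X, X.T @ dst[:, 1])
    return np.concatenate([coef_x, coef_y])


def quadratic_oracle(src, dst):
    """Independent normal-equations solution for the degree-2 fit."""
    x, y = src[:, 0], src[:, 1]
    X = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    coef_x = np.linalg.solve(X.T @ X, X.T @ dst[:, 0])
    coef_y = np.linalg.solve(X.T @ X, X.T @ dst[:, 1])
    return np.concatenate([coef_x, coef_y])


def as_pairs(src, dst):
    return [(tuple(s), tuple(d)) for s, d in zip(src, dst)]


class TestEstimateAffine:
    def test_identity(self):
        src = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        t = estimate_affine(as_pairs(src, src))
        assert np.allclose(
            [t.a, t.b, t.c, t.d, t.e, t.f], [1, 0, 0, 0, 1, 0], atol=1e-12
        )

    def test_pure_translation(self):
        src = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        t = estimate_affine(as_pairs(src, src + (5.0, 2.0)))
        assert np.allclose([t.a, t.b, t.c, t.d, t.e, t.f], [1, 0, 5, 0, 1, 2])

    def test_recovers_known_coefficients(self, rng):
        truth = AffineTransform(1.02, 0.18, -14.0, -0.05, 0.97, 9.0)
        src = rng.uniform(0, 100, size=(12, 2))
        dst = truth.apply(src)
        t = estimate_affine(as_pairs(src, dst))
        got = [t.a, t.b, t.c, t.d, t.e, t.f]
        assert np.allclose(
            got, [1.02, 0.18, -14.0, -0.05, 0.97, 9.0], atol=1e-9
        )
        assert np.max(np.abs(t.apply(src) - dst)) < 1e-9

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 50))
            src = rng.uniform(0, 100, size=(n, 2))
            dst = rng.uniform(0, 100, size=(n, 2))
            if np.linalg.matrix_rank(
                np.column_stack([src, np.ones(n)]), tol=1e-9
            ) < 3:
                continue
            t = estimate_affine(as_pairs(src, dst))
            expect = affine_oracle(src, dst)
            assert np.allclose(
                [t.a, t.b, t.c, t.d, t.e, t.f], expect, atol=1e-8
            )

    def test_underdetermined(self):
        with pytest.raises(GeometryError, match="underdetermined"):
            estimate_affine([((0, 0), (0, 0)), ((1, 1), (1, 1))])

    def test_collinear_sources(self):
        src = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(GeometryError, match="collinear"):
            estimate_affine(as_pairs(src, src))


class TestFitQuadratic:
    def test_nests_affine(self, rng):
        truth = AffineTransform(1.1, -0.1, 3.0, 0.05, 0.9, -2.0)
        src = rng.uniform(0, 100, size=(12, 2))
        q = fit_quadratic(as_pairs(src, truth.apply(src)))
        assert np.max(np.abs(list(q.px[3:]) + list(q.py[3:]))) < 1e-9
        aff = q.affine_part()
        assert np.allclose(
            [aff.a, aff.b, aff.c, aff.d, aff.e, aff.f],
            [1.1, -0.1, 3.0, 0.05, 0.9, -2.0], atol=1e-8,
        )

    def test_recovers_pure_bow(self, rng):
        src = rng.uniform(0, 100, size=(10, 2))
        dst = src.copy()
        dst[:, 0] = src[:, 0] + 0.001 * src[:, 0] ** 2
        q = fit_quadratic(as_pairs(src, dst))
        assert q.px[3] == pytest.approx(0.001, abs=1e-9)

    def test_six_generic_points_interpolate(self, rng):
        src = rng.uniform(0, 50, size=(6, 2))
        dst = rng.uniform(0, 50, size=(6, 2))
        q = fit_quadratic(as_pairs(src, dst))
        assert np.max(np.abs(q.apply(src) - dst)) < 1e-8

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 50))
            src = rng.uniform(0, 100, size=(n, 2))
            dst = src + rng.normal(0, 2.0, size=(n, 2))
            q = fit_quadratic(as_pairs(src, dst))
            expect = quadratic_oracle(src, dst)
            assert np.allclose(np.concatenate([q.px, q.py]), expect, atol=1e-8)

    def test_underdetermined(self, rng):
        src = rng.uniform(0, 10, size=(5, 2))
        with pytest.raises(GeometryError, match="underdetermined"):
            fit_quadratic(as_pairs(src, src))

    def test_rank_deficient_design(self):
        # all sources identical: design rank 1
        src = np.tile([[5.0, 5.0]], (8, 1))
        with pytest.raises(GeometryError, match="underdetermined"):
            fit_quadratic(as_pairs(src, src))


class TestWarpImage:
    def test_identity(self, rng):
        img = rng.uniform(0, 255, size=(40, 50))
        out = warp_image(img, AffineTransform.identity(), img.shape)
        assert np.allclose(out, img)

    def test_integer_translation_nearest(self, rng):
        img = rng.uniform(0, 255, size=(30, 30))
        t = AffineTransform(1, 0, 3, 0, 1, 5)
        out = warp_image(img, t, img.shape, interpolation="nearest")
        assert np.allclose(out[5:, 3:], img[:-5, :-3])
        assert np.all(out[:5, :] == 0)
        assert np.all(out[:, :3] == 0)

    def test_affine_round_trip_bound(self, rng):
        # bilinear smoothing bound holds on smooth fields (band-limited
        # random image; white noise would be low-pass filtered by design)
        from scipy.ndimage import gaussian_filter

        img = gaussian_filter(rng.uniform(0, 255, size=(60, 60)), 3.0)
        t = AffineTransform(1.01, 0.05, 2.0, -0.03, 0.99, -1.0)
        once = warp_image(img, t, img.shape)
        back = warp_image(once, t.invert(), img.shape)
        interior = np.abs(back[8:-8, 8:-8] - img[8:-8, 8:-8])
        assert interior.max() < 1.0
        smooth = np.zeros((60, 60))
        smooth[20:40, 20:40] = 100.0
        once = warp_image(smooth, t, smooth.shape)
        back = warp_image(once, t.invert(), smooth.shape)
        flat = np.abs(back[25:35, 25:35] - smooth[25:35, 25:35])
        assert flat.max() < 1.0

    def test_quadratic_warp_matches_affine_when_degenerate(self, rng):
        img = rng.uniform(0, 255, size=(40, 40))
        aff = AffineTransform(1.02, 0.03, 1.0, -0.02, 0.98, 2.0)
        quad = QuadraticTransform(
            (aff.c, aff.a, aff.b, 0.0, 0.0, 0.0),
            (aff.f, aff.d, aff.e, 0.0, 0.0, 0.0),
        )
        out_a = warp_image(img, aff, img.shape)
        out_q = warp_image(img, quad, img.shape)
        assert np.allclose(out_a, out_q, atol=1e-6)

    def test_unknown_interpolation(self):
        with pytest.raises(GeometryError):
            warp_image(np.zeros((5, 5)), AffineTransform.identity(), (5, 5),
                       interpolation="bicubic")


class TestCropToSpots:
    def test_margin_formula(self, layout):
        from microspot.detection import AnchorMatch
        from microspot import SpotRole

        refs = reference_centroids(layout)
        pos = layout.positions_with_role(SpotRole.POS)
        match = AnchorMatch(
            pairs=tuple((p, refs[p]) for p in pos), residual=0.0
        )
        img = np.zeros((600, 600))
        _, window = crop_to_spots(img, match, layout, margin_frac=0.75)
        assert window.x_min == 0  # 30 - 30
        assert window.y_min == 0
        assert window.x_max == pytest.approx(341, abs=1)  # 310 + 30 + 1
        assert window.y_max == pytest.approx(261, abs=1)

    def test_zero_margin_is_grid_bbox(self, layout):
        from microspot.detection import AnchorMatch
        from microspot import SpotRole

        refs = reference_centroids(layout)
        pos = layout.positions_with_role(SpotRole.POS)
        match = AnchorMatch(
            pairs=tuple((p, refs[p]) for p in pos), residual=0.0
        )
        img = np.zeros((600, 600))
        cropped, window = crop_to_spots(img, match, layout, margin_frac=0.0)
        assert (window.x_min, window.y_min) == (30, 30)
        assert window.x_max == pytest.approx(311, abs=1)

    def test_clamped_to_image_bounds(self, layout):
        from microspot.detection import AnchorMatch
        from microspot import SpotRole

        refs = reference_centroids(layout)
        pos = layout.positions_with_role(SpotRole.POS)
        # grid partially outside a small image: clamp, no error
        match = AnchorMatch(
            pairs=tuple((p, refs[p]) for p in pos), residual=0.0
        )
        img = np.zeros((200, 200))
        cropped, window = crop_to_spots(img, match, layout, margin_frac=0.75)
        assert window.x_max <= 200 and window.y_max <= 200
        assert cropped.shape == (window.y_max - window.y_min,
                                 window.x_max - window.x_min)


def pos_centroid_residual(std_img, layout, config=None):
    """Max distance between detected POS centroids and the reference grid."""
    from microspot.detection import default_quantile

    config = config or AnalysisConfig()
    mask = threshold_mask(
        std_img, "quantile", default_quantile(layout, std_img)
    )
    blobs = find_blobs(mask, config.resolve_min_area(layout))
    match = match_anchors(blobs, layout)
    refs = reference_centroids(layout)
    dists = [
        np.hypot(c[0] - refs[p][0], c[1] - refs[p][1]) for p, c in match.pairs
    ]
    return max(dists), len(match.pairs)


class TestStandardize:
    def test_identity_aberration_residual_below_half_pixel(self, layout):
        spec = SceneSpec(seed=11, aberration=Aberration(), noise_sd=0.0,
                         noise_scale=0.0)
        rgb, _ = render(spec)
        std = standardize(to_luminance(rgb), layout)
        residual, n = pos_centroid_residual(std, layout)
        assert n >= 12
        assert residual < 0.5

    def test_shear_and_bow_residual_below_one_pixel(self, mild_scene, layout):
        _, lum, _ = mild_scene
        std = standardize(lum, layout)
        residual, n = pos_centroid_residual(std, layout)
        assert n >= 10
        assert residual < 1.0

    def test_idempotent_within_tolerance(self, mild_scene, layout):
        _, lum, _ = mild_scene
        std = standardize(lum, layout)
        again = standardize(std, layout)
        residual, _ = pos_centroid_residual(again, layout)
        assert residual < 0.5

    def test_survives_four_occluded_anchors(self, layout):
        # occlude 4 non-corner ring POS spots; >= 6 anchors remain
        from microspot import SpotRole

        ring = layout.outer_ring()
        pos_ring = [
            p for p in layout.positions_with_role(SpotRole.POS)
            if p in ring and p not in layout.corners()
        ]
        occluded = {p: 0.0 for p in pos_ring[:4]}
        spec = SceneSpec(
            seed=5,
            spot_overrides=occluded,
            aberration=Aberration(shear_deg=4.0, bow=(8e-5, -6e-5)),
        )
        rgb, _ = render(spec)
        std = standardize(to_luminance(rgb), layout)
        residual, n = pos_centroid_residual(std, layout)
        assert n >= 6
        assert residual < 1.5

    def test_blank_image_fails_in_detection_stage(self, layout):
        from microspot.errors import DetectionError

        with pytest.raises(DetectionError):
            standardize(np.zeros((360, 440)), layout)

    def test_output_shape_follows_layout(self, layout):
        spec = SceneSpec(seed=2)
        rgb, _ = render(spec)
        std = standardize(to_luminance(rgb), layout)
        assert std.shape == standardized_shape(layout)
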