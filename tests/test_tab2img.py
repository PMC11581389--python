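"""Image transformation: normalisation, embedding, geometry, rasterisation.

Geometry and embedding are checked against independent oracles: a brute-force
O(m^3) hull, an edge-orientation area sweep, shapely's minimum rotated
rectangle, and a from-scratch centered-kernel eigendecomposition.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import clinimage as ci
from clinimage.tab2img import (
    EmbeddingError,
    apply_normalization,
    fit_normalization,
    rasterize_layout,
    render_image,
)


class TestNormalization:
    def test_min_max_learned_from_training_rows(self):
        params = fit_normalization(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_allclose(params.mins, [0.0])
        np.testing.assert_allclose(params.maxs, [10.0])
        out = apply_normalization(np.array([[0.0], [5.0], [10.0]]), params)
        np.testing.assert_allclose(out.ravel(), [0.0, 0.5, 1.0])

    def test_out_of_range_test_values_clipped(self):
        params = fit_normalization(np.array([[0.0], [10.0]]))
        out = apply_normalization(np.array([[12.0], [-3.0]]), params)
        np.testing.assert_allclose(out.ravel(), [1.0, 0.0])

    def test_constant_feature_maps_to_zero(self):
        params = fit_normalization(np.array([[4.0], [4.0]]))
        assert params.mins[0] == params.maxs[0] == 4.0
        out = apply_normalization(np.array([[4.0], [7.0]]), params)
        np.testing.assert_allclose(out.ravel(), [0.0, 0.0])


class TestKpcaEmbedding:
    def _oracle(self, x, sigma):
        """Independent dense eigendecomposition of the centered Gaussian kernel."""
        from scipy.linalg import eigh
        from scipy.spatial.distance import cdist

        pts = x.T
        k = np.exp(-cdist(pts, pts, "sqeuclidean") / (2 * sigma**2))
        n = k.shape[0]
        one = np.ones((n, n)) / n
        kc = k - one @ k - k @ one + one @ k @ one
        w, v = eigh(kc)
        scores = v[:, [-1, -2]] * np.sqrt(w[[-1, -2]])
        return scores

    def test_matches_independent_eigendecomposition(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 5))
        coords, sigma = ci.kpca_embed_features(x, sigma=0.8)
        oracle = self._oracle(x, 0.8)
        for k in range(2):  # sign-align each component before comparing
            o = oracle[:, k]
            if np.sign(o[np.argmax(np.abs(o))]) != np.sign(
                coords[np.argmax(np.abs(coords[:, k])), k]
            ):
                o = -o
            np.testing.assert_allclose(coords[:, k], o, atol=1e-8)

    def test_identical_feature_columns_coincide(self):
        rng = np.random.default_rng(1)
        col = rng.random((8, 1))
        x = np.hstack([col, col, rng.random((8, 3))])
        coords, _ = ci.kpca_embed_features(x)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-9)

    def test_components_have_zero_mean(self):
        rng = np.random.default_rng(2)
        coords, _ = ci.kpca_embed_features(rng.random((10, 7)))
        assert np.all(np.abs(coords.mean(axis=0)) < 1e-9)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(3)
        coords, _ = ci.kpca_embed_features(rng.random((9, 6)))
        for k in range(2):
            assert coords[np.argmax(np.abs(coords[:, k])), k] > 0

    def test_degenerate_kernel_raises(self):
        x = np.ones((5, 4))  # all feature points coincide
        with pytest.raises((EmbeddingError, ValueError)):
            ci.kpca_embed_features(x, sigma=1.0)


def _cross2(u: np.ndarray, v: np.ndarray) -> float:
    return float(u[0] * v[1] - u[1] * v[0])


def _brute_force_hull(points: np.ndarray) -> set[tuple[float, float]]:
    """A point is a hull vertex iff it lies outside the hull of the others:
    equivalently, not expressible as a convex combination witnessed by being
    inside some triangle of other points (O(m^3) per point)."""
    verts = set()
    for i, p in enumerate(points):
        others = np.delete(points, i, axis=0)
        inside = False
        for a, b, c in itertools.combinations(others, 3):
            d1 = _cross2(b - a, p - a)
            d2 = _cross2(c - b, p - b)
            d3 = _cross2(a - c, p - c)
            if (d1 >= -1e-12 and d2 >= -1e-12 and d3 >= -1e-12) or (
                d1 <= 1e-12 and d2 <= 1e-12 and d3 <= 1e-12
            ):
                inside = True
                break
        if not inside:
            verts.add((round(p[0], 9), round(p[1], 9)))
    return verts


class TestConvexHull:
    def test_square_with_center(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]], dtype=float)
        hull = ci.convex_hull(pts)
        assert len(hull) == 4
        assert {tuple(v) for v in hull} == {(0, 0), (1, 0), (1, 1), (0, 1)}

    def test_counter_clockwise_from_lexicographic_start(self):
        hull = ci.convex_hull(np.array([[0, 0], [2, 0], [2, 2], [0, 2]], float))
        np.testing.assert_array_equal(hull[0], [0, 0])
        area2 = sum(
            _cross2(hull[i], hull[(i + 1) % len(hull)]) for i in range(len(hull))
        )
        assert area2 > 0  # positive signed area: counter-clockwise

    def test_collinear_returns_two_extremes(self):
        pts = np.array([[i, 2 * i] for i in range(5)], dtype=float)
        hull = ci.convex_hull(pts)
        assert len(hull) == 2
        np.testing.assert_array_equal(hull, [[0, 0], [4, 8]])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.random((30, 2))
        hull = ci.convex_hull(pts)
        got = {(round(v[0], 9), round(v[1], 9)) for v in hull}
        assert got == _brute_force_hull(pts)

    def test_matches_scipy_qhull(self):
        from scipy.spatial import ConvexHull as QHull

        rng = np.random.default_rng(5)
        pts = rng.random((40, 2))
        got = {tuple(v) for v in ci.convex_hull(pts)}
        expected = {tuple(pts[i]) for i in QHull(pts).vertices}
        assert got == expected


class TestMinAreaRect:
    def test_axis_aligned_unit_square(self):
        rect = ci.min_area_rect(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        (_, _), w, h, angle = rect
        assert w * h == pytest.approx(1.0, abs=1e-12)
        assert angle == pytest.approx(0.0, abs=1e-9)

    def test_square_rotated_45_degrees(self):
        c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
        rot = np.array([[c, -s], [s, c]])
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float) @ rot.T
        (_, _), w, h, angle = ci.min_area_rect(ci.convex_hull(pts))
        assert w * h == pytest.approx(1.0, abs=1e-9)
        assert angle == pytest.approx(45.0, abs=1e-6)

    def test_matches_orientation_sweep_and_shapely(self):
        import shapely.geometry as geom

        rng = np.random.default_rng(6)
        pts = rng.random((25, 2)) * np.array([3.0, 1.0])
        hull = ci.convex_hull(pts)
        (_, _), w, h, angle = ci.min_area_rect(hull)
        # oracle 1: exhaustive sweep over hull-edge orientations
        areas = []
        closed = np.vstack([hull, hull[:1]])
        for e in np.diff(closed, axis=0):
            theta = np.arctan2(e[1], e[0])
            c, s = np.cos(theta), np.sin(theta)
            proj = pts @ np.array([[c, s], [-s, c]]).T
            ext = proj.max(axis=0) - proj.min(axis=0)
            areas.append(ext[0] * ext[1])
        assert w * h == pytest.approx(min(areas), abs=1e-9)
        # oracle 2: shapely minimum rotated rectangle
        shp = geom.MultiPoint([tuple(p) for p in pts]).minimum_rotated_rectangle
        assert w * h == pytest.approx(shp.area, rel=1e-9)
        # never worse than the axis-aligned bounding box
        bbox = np.prod(pts.max(axis=0) - pts.min(axis=0))
        assert w * h <= bbox + 1e-12

    def test_degenerate_segment_gets_zero_height(self):
        hull = ci.convex_hull(np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float))
        (_, _), w, h, angle = ci.min_area_rect(hull)
        assert min(w, h) == pytest.approx(0.0, abs=1e-12)
        assert max(w, h) == pytest.approx(np.hypot(3, 3), abs=1e-9)


class TestRasterize:
    def test_corner_features_hit_grid_corners(self):
        coords = np.array([[0, 0], [10, 0], [10, 4], [0, 4]], dtype=float)
        rect = ci.min_area_rect(ci.convex_hull(coords))
        pixels, groups = rasterize_layout(coords, rect, (10, 10))
        assert {tuple(p) for p in pixels} == {(0, 0), (0, 9), (9, 0), (9, 9)}
        assert len(groups) == 4

    def test_identical_coords_share_pixel_and_group(self):
        coords = np.array([[0, 0], [1, 1], [1, 1], [2, 0.2]], dtype=float)
        rect = ci.min_area_rect(ci.convex_hull(coords))
        pixels, groups = rasterize_layout(coords, rect, (8, 8))
        np.testing.assert_array_equal(pixels[1], pixels[2])
        assert [1, 2] in groups

    def test_pixel_conservation_invariant(self):
        rng = np.random.default_rng(7)
        coords = rng.random((28, 2))
        rect = ci.min_area_rect(ci.convex_hull(coords))
        pixels, groups = rasterize_layout(coords, rect, (12, 12))
        distinct = len({tuple(p) for p in pixels})
        assert distinct + sum(len(g) - 1 for g in groups) == 28
        assert all(0 <= r < 12 and 0 <= c < 12 for r, c in pixels)

    def test_tiny_grid_rejected(self):
        coords = np.random.default_rng(8).random((5, 2))
        rect = ci.min_area_rect(ci.convex_hull(coords))
        with pytest.raises(ValueError):
            rasterize_layout(coords, rect, (1, 5))


class TestRenderAndTransformer:
    def test_zero_patient_gives_zero_image(self, fitted_imager):
        img = render_image(np.zeros(28), fitted_imager.layout_)
        assert not img.pixels.any()

    def test_collision_group_averages_values(self):
        coords = np.array([[0, 0], [0, 0], [1, 0], [0, 1]], dtype=float)
        rect = ci.min_area_rect(ci.convex_hull(coords))
        pixels, groups = rasterize_layout(coords, rect, (4, 4))
        layout = ci.FeatureLayout(coords, 1.0, ci.convex_hull(coords), rect,
                                  (4, 4), pixels, groups)
        img = render_image(np.array([0.2, 0.8, 0.5, 0.5]), layout)
        r, c = pixels[0]
        assert img.pixels[r, c] == pytest.approx(0.5)

    def test_transform_reproduces_fit_transform(self, separable_split, fitted_imager):
        train, _, _ = separable_split
        again = ci.TableToImageTransformer().fit(train.values)
        np.testing.assert_array_equal(
            again.transform(train.values), fitted_imager.transform(train.values)
        )

    def test_new_identical_patient_gets_identical_image(self, separable_split,
                                                        fitted_imager):
        train, _, _ = separable_split
        imgs = fitted_imager.transform(train.values[:3])
        dup = fitted_imager.transform(train.values[[1]])
        np.testing.assert_array_equal(dup[0], imgs[1])

    def test_layout_fit_is_deterministic(self, separable_split):
        train, _, _ = separable_split
        a = ci.TableToImageTransformer().fit(train.values).layout_
        b = ci.TableToImageTransformer().fit(train.values).layout_
        np.testing.assert_array_equal(a.coords, b.coords)
        np.testing.assert_array_equal(a.pixel_of_feature, b.pixel_of_feature)

    def test_test_set_cannot_influence_layout(self, separable_split):
        """Leakage contract: mutating test rows leaves every layout field alone."""
        train, test, _ = separable_split
        t1 = ci.TableToImageTransformer().fit(train.values)
        mutated = test.values * 3.0 + 17.0
        t1.transform(mutated)
        t2 = ci.TableToImageTransformer().fit(train.values)
        np.testing.assert_array_equal(t1.layout_.coords, t2.layout_.coords)
        np.testing.assert_array_equal(
            t1.layout_.pixel_of_feature, t2.layout_.pixel_of_feature
        )
        np.testing.assert_array_equal(t1.norm_params_.mins, t2.norm_params_.mins)

    def test_intensity_monotone_for_noncolliding_feature(self, fitted_imager):
        layout = fitted_imager.layout_
        solo = next(g[0] for g in layout.collision_groups if len(g) == 1)
        r, c = layout.pixel_of_feature[solo]
        lo = np.zeros((1, 28))
        hi = np.zeros((1, 28))
        lo[0, solo], hi[0, solo] = 0.2, 0.9
        # bypass normalisation scaling by rendering normalised rows directly
        img_lo = render_image(lo[0], layout).pixels[r, c]
        img_hi = render_image(hi[0], layout).pixels[r, c]
        assert img_hi > img_lo

    def test_layout_json_round_trip(self, fitted_imager, tmp_path):
        layout = fitted_imager.layout_
        layout.to_json(tmp_path / "layout.json")
        loaded = ci.FeatureLayout.from_json(tmp_path / "layout.json")
        np.testing.assert_allclose(loaded.coords, layout.coords)
        np.testing.assert_array_equal(loaded.pixel_of_feature,
                                      layout.pixel_of_feature)
        assert loaded.collision_groups == layout.collision_groups

    def test_png_round_trip_quantised(self, fitted_imager, tmp_path, separable_split):
        from PIL import Image

        train, _, _ = separable_split
        img = render_image(
            apply_normalization(train.values[:1], fitted_imager.norm_params_)[0],
            fitted_imager.layout_,
        )
        img.to_png(tmp_path / "p.png")
        back = np.asarray(Image.open(tmp_path / "p.png"), dtype=float) / 255.0
        np.testing.assert_allclose(back, img.pixels, atol=1 / 255.0 + 1e-9)
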