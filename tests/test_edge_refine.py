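import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from portaledge import (
    IntensityGrid,
    MarkerSet,
    RefineConfig,
    compute_gradient_image,
    curve_gradient_objective,
    detect_border_point,
    fit_edge_curve,
    overlay_curves,
    refine_edge,
)
from portaledge.edge_refine import (
    DisjointDomainsError,
    DuplicateAbscissaeError,
    NoEdgeError,
    OutOfBoundsError,
    SearchBoxError,
)


def gradient_loop_oracle(vals, mode="abs"):
    """Element-wise forward-difference gradient, written as plain loops."""
    n, m = vals.shape
    out = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            dx = vals[i + 1, j] - vals[i, j] if i + 1 < n else 0.0
            dy = vals[i, j + 1] - vals[i, j] if j + 1 < m else 0.0
            out[i, j] = dx + dy if mode == "signed" else abs(dx) + abs(dy)
    return out


class TestGradientImage:
    @pytest.mark.parametrize("mode", ["abs", "signed"])
    def test_constant_image_has_zero_gradient(self, mode):
        img = IntensityGrid(np.full((6, 7), 7.0), 1.0)
        assert np.all(compute_gradient_image(img, mode).values == 0)

    @pytest.mark.parametrize("mode", ["abs", "signed"])
    def test_unit_ramp_gradient_is_one_in_interior(self, mode):
        vals = np.tile(np.arange(8.0)[:, None], (1, 8))  # I(i,j) = i
        g = compute_gradient_image(IntensityGrid(vals, 1.0), mode).values
        assert np.all(g[:-1, :] == 1.0)
        assert np.all(g[-1, :] == 0.0)

    def test_binary_step_matches_loop_oracle(self):
        vals = np.zeros((4, 4))
        vals[:, 2:] = 100.0
        for mode in ("abs", "signed"):
            g = compute_gradient_image(IntensityGrid(vals, 1.0), mode).values
            np.testing.assert_array_equal(g, gradient_loop_oracle(vals, mode))

    @given(
        vals=hnp.arrays(
            np.float64,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=7),
            elements=st.floats(-100, 100),
        )
    )
    def test_signed_sum_telescopes_and_matches_oracle(self, vals):
        g = compute_gradient_image(IntensityGrid(vals, 1.0), "signed").values
        np.testing.assert_allclose(g, gradient_loop_oracle(vals, "signed"), atol=1e-9)
        # forward differences telescope to boundary terms
        expected = (vals[-1, :] - vals[0, :]).sum() + (vals[:, -1] - vals[:, 0]).sum()
        assert g.sum() == pytest.approx(expected, abs=1e-7)


class TestBorderPoint:
    def test_step_edge_matches_argmax_oracle(self):
        vals = np.zeros((32, 32))
        vals[17:, :] = 500.0  # horizontal step edge: max dx at row 16
        img = IntensityGrid(vals, 1.0)
        point = detect_border_point(img, (13, 10), "vertical", 8)
        # independent argmax over the profile pixels
        grad = gradient_loop_oracle(vals)
        profile_rows = np.arange(13 - 8, 13 + 9)
        oracle_row = profile_rows[np.argmax(grad[profile_rows, 10])]
        assert point == (oracle_row, 10) == (16, 10)

    def test_blurred_step_matches_argmax_oracle(self):
        rows = np.arange(40)[:, None]
        vals = np.tile(1000.0 / (1 + np.exp(-(rows - 21.3) / 1.7)), (1, 40))
        img = IntensityGrid(vals, 1.0)
        point = detect_border_point(img, (18, 20), "vertical", 9)
        grad = gradient_loop_oracle(vals)
        profile_rows = np.arange(9, 28)
        assert point[0] == profile_rows[np.argmax(grad[profile_rows, 20])]

    def test_horizontal_direction(self):
        vals = np.zeros((16, 16))
        vals[:, 9:] = 80.0
        assert detect_border_point(IntensityGrid(vals, 1.0), (7, 6), "horizontal", 5) == (7, 8)

    def test_tie_breaks_prefer_nearest_then_lower_index(self):
        vals = np.zeros((21, 5))
        vals[5, 2] = 10.0  # two equal-magnitude gradient spikes around row 5
        vals[15, 2] = 10.0  # ... and around row 15, symmetric about seed row 10
        img = IntensityGrid(vals, 1.0)
        # equal |gradient| maxima at rows 4,5 and 14,15; rows 5 and 14 are
        # nearest to the seed (distance 5 before 14 -> distance 4)
        assert detect_border_point(img, (10, 2), "vertical", 9) == (5, 2)

    def test_constant_profile_is_no_edge(self):
        img = IntensityGrid(np.full((16, 16), 3.0), 1.0)
        with pytest.raises(NoEdgeError):
            detect_border_point(img, (8, 8), "vertical", 5)

    def test_profile_must_stay_inside(self):
        img = IntensityGrid(np.zeros((16, 16)), 1.0)
        with pytest.raises(OutOfBoundsError):
            detect_border_point(img, (2, 8), "vertical", 5)


class TestCubicFit:
    def test_recovers_known_cubic(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 2 * x**3 - x + 5
        curve = fit_edge_curve(MarkerSet(np.column_stack([y, x])), orientation="y_of_x")
        np.testing.assert_allclose(curve.coeffs, (2, 0, -1, 5), atol=1e-9)
        assert curve.domain == (0.0, 3.0)

    def test_collinear_markers_degenerate_to_line(self):
        x = np.array([0.0, 2.0, 5.0, 9.0])
        y = 3 * x + 1
        curve = fit_edge_curve(MarkerSet(np.column_stack([y, x])), orientation="y_of_x")
        np.testing.assert_allclose(curve.coeffs, (0, 0, 3, 1), atol=1e-9)

    def test_duplicate_abscissae_rejected(self):
        pts = np.array([[0.0, 1.0], [5.0, 1.0], [2.0, 3.0], [1.0, 4.0]])
        with pytest.raises(DuplicateAbscissaeError):
            fit_edge_curve(MarkerSet(pts), orientation="y_of_x")

    def test_orientation_flips_for_near_vertical_edges(self):
        # markers spanning many rows but few columns -> col = f(row)
        pts = np.array([[0.0, 10.0], [12.0, 11.0], [25.0, 10.5], [40.0, 12.0]])
        assert fit_edge_curve(MarkerSet(pts)).orientation == "x_of_y"

    @given(
        coeffs=st.tuples(*[st.floats(-2, 2) for _ in range(4)]),
        xs=st.lists(
            st.floats(-8, 8), min_size=4, max_size=4, unique_by=lambda v: round(v, 2)
        ),
    )
    def test_interpolation_exactness_on_random_cubics(self, coeffs, xs):
        x = np.array(sorted(xs))
        if np.min(np.diff(x)) < 0.05:
            return  # keep the Vandermonde well-conditioned
        y = np.polyval(coeffs, x)
        curve = fit_edge_curve(MarkerSet(np.column_stack([y, x])), orientation="y_of_x")
        np.testing.assert_allclose(curve(x), y, atol=1e-6)
        np.testing.assert_allclose(curve.coeffs, coeffs, atol=1e-5)


class TestObjective:
    def _line_markers(self, row, cols=(4.0, 12.0, 20.0, 28.0)):
        return MarkerSet(np.array([[row, c] for c in cols]))

    def test_zero_gradient_image_gives_zero(self):
        grad = IntensityGrid(np.zeros((32, 32)), 1.0)
        curve = fit_edge_curve(self._line_markers(10.0))
        assert curve_gradient_objective(grad, curve, "sum") == 0.0
        assert curve_gradient_objective(grad, curve, "mean") == 0.0

    def test_uniform_gradient_sum_and_mean(self):
        grad = IntensityGrid(np.full((32, 32), 3.5), 1.0)
        curve = fit_edge_curve(self._line_markers(10.0))
        n_samples = len(curve.integer_abscissae())
        assert n_samples == 25
        assert curve_gradient_objective(grad, curve, "sum") == pytest.approx(3.5 * n_samples)
        assert curve_gradient_objective(grad, curve, "mean") == pytest.approx(3.5)

    def test_on_ridge_beats_off_ridge(self):
        vals = np.zeros((32, 32))
        vals[15, :] = 100.0  # bright gradient ridge on row 15
        grad = IntensityGrid(vals, 1.0)
        on = curve_gradient_objective(grad, fit_edge_curve(self._line_markers(15.0)), "mean")
        off = curve_gradient_objective(grad, fit_edge_curve(self._line_markers(18.0)), "mean")
        assert on > off

    def test_curve_exiting_image_is_an_error(self):
        grad = IntensityGrid(np.zeros((16, 16)), 1.0)
        pts = np.array([[2.0, 0.0], [30.0, 5.0], [2.0, 10.0], [2.0, 15.0]])
        with pytest.raises(OutOfBoundsError):
            curve_gradient_objective(grad, fit_edge_curve(MarkerSet(pts), "y_of_x"))


def jittered_markers(boundary, cols, jitter, rng):
    pts = np.array(
        [[boundary(c) + rng.uniform(-jitter, jitter), c + rng.uniform(-jitter, jitter)]
         for c in cols]
    )
    return MarkerSet(pts)


def exhaustive_grid_best(img, markers, radius_px, free, mode="mean"):
    """Brute-force enumeration of every integer offset combination."""
    grad = compute_gradient_image(img, "abs")
    base = markers.points
    best = -np.inf
    steps = range(-radius_px, radius_px + 1)
    for offs in itertools.product(steps, repeat=2 * len(free)):
        pts = base.copy()
        pts[list(free)] += np.array(offs, dtype=float).reshape(len(free), 2)
        try:
            val = curve_gradient_objective(grad, fit_edge_curve(MarkerSet(pts)), mode)
        except (DuplicateAbscissaeError, OutOfBoundsError, ValueError):
            continue
        best = max(best, val)
    return best


class TestRefineEdge:
    def test_zero_radius_returns_input_markers(self, edge_image):
        img, boundary = edge_image
        markers = jittered_markers(boundary, (14, 26, 38, 50), 0.0, np.random.default_rng(0))
        cfg = RefineConfig(seed=1, search_radius_mm=0.0)
        refined, curve, objective = refine_edge(img, markers, cfg)
        np.testing.assert_array_equal(refined.points, markers.points)
        grad = compute_gradient_image(img, "abs")
        assert objective == pytest.approx(curve_gradient_objective(grad, curve, "mean"))

    def test_seeded_runs_are_bit_identical(self, edge_image):
        img, boundary = edge_image
        markers = jittered_markers(boundary, (14, 26, 38, 50), 1.5, np.random.default_rng(3))
        cfg = RefineConfig(seed=42, search_radius_mm=2.0)
        r1 = refine_edge(img, markers, cfg)
        r2 = refine_edge(img, markers, cfg)
        np.testing.assert_array_equal(r1[0].points, r2[0].points)
        assert r1[2] == r2[2]

    def test_objective_never_below_initial(self, edge_image):
        img, boundary = edge_image
        grad = compute_gradient_image(img, "abs")
        for seed in (0, 1, 2):
            markers = jittered_markers(
                boundary, (14, 26, 38, 50), 2.0, np.random.default_rng(seed)
            )
            initial = curve_gradient_objective(grad, fit_edge_curve(markers), "mean")
            _, _, refined_obj = refine_edge(img, markers, RefineConfig(seed=seed))
            assert refined_obj >= initial - 1e-12

    def test_recovers_sharp_edge_within_one_pixel(self, edge_image):
        img, boundary = edge_image
        rng = np.random.default_rng(7)
        markers = jittered_markers(boundary, (14, 26, 38, 50), 2.0, rng)
        refined, curve, _ = refine_edge(img, markers, RefineConfig(seed=7))
        cols = refined.points[:, 1]
        # the gradient ridge sits just above the step row
        np.testing.assert_allclose(refined.points[:, 0], boundary(cols), atol=1.0)

    def test_search_box_must_fit_inside_image(self, edge_image):
        img, _ = edge_image
        pts = np.array([[1.0, 2.0], [20.0, 20.0], [30.0, 40.0], [40.0, 60.0]])
        with pytest.raises(SearchBoxError):
            refine_edge(img, MarkerSet(pts), RefineConfig(seed=0, search_radius_mm=3.0))

    def test_matches_exhaustive_grid_two_free_markers(self, edge_image):
        img, boundary = edge_image
        markers = jittered_markers(boundary, (14, 26, 38, 50), 1.5, np.random.default_rng(5))
        free = (1, 2)
        grid_best = exhaustive_grid_best(img, markers, 3, free)
        _, _, refined_obj = refine_edge(
            img, markers, RefineConfig(seed=11, search_radius_mm=3.0), free_markers=free
        )
        assert refined_obj >= grid_best - 1e-6

    def test_matches_exhaustive_grid_all_markers_radius_one(self, edge_image):
        img, boundary = edge_image
        markers = jittered_markers(boundary, (14, 26, 38, 50), 1.0, np.random.default_rng(9))
        grid_best = exhaustive_grid_best(img, markers, 1, (0, 1, 2, 3))
        _, _, refined_obj = refine_edge(
            img, markers, RefineConfig(seed=13, search_radius_mm=1.0)
        )
        assert refined_obj >= grid_best - 1e-6


class TestOverlay:
    def _curve(self, offset=0.0):
        pts = np.array([[10.0 + offset, 4.0], [11.0 + offset, 14.0],
                        [12.5 + offset, 24.0], [15.0 + offset, 34.0]])
        return fit_edge_curve(MarkerSet(pts), orientation="y_of_x")

    def test_identical_curves_score_zero(self):
        fused = IntensityGrid(np.zeros((40, 40)), 1.0)
        _, score = overlay_curves(self._curve(), self._curve(), fused)
        assert score == pytest.approx(0.0, abs=1e-9)

    def test_constant_vertical_offset_of_flat_curves(self):
        flat = lambda row: fit_edge_curve(
            MarkerSet(np.array([[row, c] for c in (4.0, 14.0, 24.0, 34.0)])),
            orientation="y_of_x",
        )
        fused = IntensityGrid(np.zeros((40, 40)), 1.0)
        _, score = overlay_curves(flat(10.0), flat(12.0), fused)
        assert score == pytest.approx(2.0, abs=1e-6)

    def test_rendered_png_roundtrips_as_rgb(self, tmp_path):
        from PIL import Image

        fused = IntensityGrid(np.linspace(0, 100, 1600).reshape(40, 40), 1.0)
        canvas, _ = overlay_curves(self._curve(), self._curve(2.0), fused, tmp_path / "o.png")
        with Image.open(tmp_path / "o.png") as im:
            back = np.asarray(im)
        assert back.shape == (40, 40, 3)
        np.testing.assert_array_equal(back, canvas)

    def test_disjoint_domains_rejected(self):
        fused = IntensityGrid(np.zeros((40, 40)), 1.0)
        a = fit_edge_curve(
            MarkerSet(np.array([[10.0, c] for c in (0.0, 3.0, 6.0, 9.0)])), "y_of_x"
        )
        b = fit_edge_curve(
            MarkerSet(np.array([[10.0, c] for c in (20.0, 25.0, 30.0, 35.0)])), "y_of_x"
        )
        with pytest.raises(DisjointDomainsError):
            overlay_curves(a, b, fused)
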