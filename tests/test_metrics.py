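import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oneback.behavior import generate_session
from oneback.metrics import (
    METRIC_COLUMNS,
    MetricConfig,
    area,
    aspect_ratio,
    aspect_ratio_dissimilarity,
    compactness,
    compute_dissimilarity_table,
    curvature_cdf_sse,
    hausdorff_distance,
    hull_area,
    intersection_over_union,
    local_angle_distribution,
    scalar_sq_diff,
    turning_distance,
    turning_function,
)
from oneback.shapes import ClosedCurve, ShapeOutline, resample_perimeter, rotate_shape

from conftest import circle_outline, rectangle_outline, square_outline
from oracles import (
    brute_cdf_sse,
    brute_hausdorff,
    brute_iou,
    brute_turning_distance,
)


def random_polygon(n, rng, r_lo=5.0, r_hi=12.0):
    """Star-shaped (hence simple) polygon with random radii."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = rng.uniform(r_lo, r_hi, n)
    return ShapeOutline(points=np.column_stack([r * np.cos(ang), r * np.sin(ang)]))


class TestLocalAngles:
    def test_straight_edge_gives_180(self):
        # 20 mm sides: points >= 5 mm from both corners keep both half-span
        # chords inside one edge, giving exactly 180 degrees
        big = square_outline(side_mm=20.0, spacing_mm=0.1)
        cdf = local_angle_distribution(big)
        assert np.sum(np.abs(cdf.samples - 180.0) < 1e-9) >= 4 * 101

    def test_circle_closed_form(self, circle):
        cdf = local_angle_distribution(circle)
        # every point of a circle sees the same angle ...
        assert cdf.samples.max() - cdf.samples.min() < 1e-3
        # ... equal to 180 - (180/pi) * (half-span arc / radius) up to the
        # ~5e-4 relative discretization of the 0.1 mm resampling
        nominal = 180.0 - (180.0 / np.pi) * (5.0 / 12.5)
        np.testing.assert_allclose(cdf.samples, nominal, atol=0.05)

    def test_rotation_invariance(self, small_pool):
        shape = next(iter(small_pool.values()))
        a = local_angle_distribution(shape)
        b = local_angle_distribution(rotate_shape(shape, 90.0))
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-9)

    def test_span_too_large_errors(self):
        tri = ShapeOutline(points=np.array([[0, 0], [1, 0], [0, 1]], float))
        with pytest.raises(ValueError, match="span"):
            local_angle_distribution(tri)


class TestCurvatureCDF:
    def test_identity_zero(self, circle):
        cdf = local_angle_distribution(circle)
        assert curvature_cdf_sse(cdf, cdf) == 0.0

    def test_symmetry(self, small_pool):
        shapes = list(small_pool.values())
        cdfs = [local_angle_distribution(s) for s in shapes[:5]]
        for i in range(len(cdfs)):
            for j in range(i + 1, len(cdfs)):
                assert curvature_cdf_sse(cdfs[i], cdfs[j]) == pytest.approx(
                    curvature_cdf_sse(cdfs[j], cdfs[i]), abs=0
                )

    def test_brute_force_oracle(self, circle, square):
        a = local_angle_distribution(circle)
        b = local_angle_distribution(square)
        grid = np.arange(0.0, 360.5, 0.5)
        assert curvature_cdf_sse(a, b) == pytest.approx(
            brute_cdf_sse(a.samples, b.samples, grid), abs=1e-12
        )

    def test_mismatched_grids_error(self, circle):
        a = local_angle_distribution(circle, MetricConfig(span_points=101))
        b = local_angle_distribution(circle, MetricConfig(span_points=51))
        with pytest.raises(ValueError, match="span"):
            curvature_cdf_sse(a, b)


class TestAspectRatio:
    def test_rectangle(self):
        rect = rectangle_outline(2.0, 1.0, spacing_mm=0.05)
        assert aspect_ratio(rect) == pytest.approx(2.0, abs=1e-9)

    def test_circle_and_square_are_one(self, circle, square):
        assert aspect_ratio(circle) == pytest.approx(1.0, abs=1e-4)
        assert aspect_ratio(square) == pytest.approx(1.0, abs=1e-9)
        # brute-force: square width equals height at every rotation
        for ang in range(0, 360, 15):
            r = rotate_shape(square, float(ang))
            spans = r.points.max(axis=0) - r.points.min(axis=0)
            assert spans[0] / spans[1] <= np.sqrt(2.0) + 1e-9

    def test_dissimilarity_identity(self, square):
        for mode in ("actual", "optimal"):
            assert aspect_ratio_dissimilarity(square, square, mode) == 0.0

    def test_rect_rotated_90(self):
        rect = rectangle_outline(2.0, 1.0, spacing_mm=0.05)
        rot = rotate_shape(rect, 90.0)
        assert aspect_ratio_dissimilarity(rect, rot, "actual") == pytest.approx(
            2.25, abs=1e-6
        )
        assert aspect_ratio_dissimilarity(rect, rot, "optimal") == pytest.approx(
            0.0, abs=1e-9
        )

    def test_optimal_orientation_invariant(self, small_pool):
        shapes = list(small_pool.values())
        a, b = shapes[0], shapes[1]
        base = aspect_ratio_dissimilarity(a, b, "optimal")
        for ka in (0, 90, 180, 270):
            for kb in (0, 90, 180, 270):
                v = aspect_ratio_dissimilarity(
                    rotate_shape(a, ka), rotate_shape(b, kb), "optimal"
                )
                assert v == pytest.approx(base, rel=1e-6, abs=1e-9)


class TestAreaFamily:
    def test_unit_square(self):
        sq = square_outline(side_mm=1.0, spacing_mm=0.01)
        assert area(sq) == pytest.approx(1.0, abs=1e-9)
        assert hull_area(sq) == pytest.approx(1.0, abs=1e-9)
        assert compactness(sq) == pytest.approx(1.0, abs=1e-9)

    def test_convex_compactness_one(self, circle):
        assert compactness(circle) == pytest.approx(1.0, abs=1e-6)

    def test_notched_square(self):
        # 10x10 square minus a 5x5 notch cut into the top edge: area 75,
        # hull 100 (a notch at a corner would shave the hull diagonally)
        pts = np.array(
            [
                [0, 0], [10, 0], [10, 10], [7.5, 10], [7.5, 5],
                [2.5, 5], [2.5, 10], [0, 10],
            ],
            float,
        )
        shape = resample_perimeter(ClosedCurve(points=pts), 0.1)
        assert area(shape) == pytest.approx(75.0, abs=1e-9)
        assert hull_area(shape) == pytest.approx(100.0, abs=1e-9)
        assert compactness(shape) == pytest.approx(0.75, abs=1e-9)

    def test_self_intersecting_errors(self):
        bow = ShapeOutline(points=np.array([[0, 0], [1, 1], [1, 0], [0, 1]], float))
        with pytest.raises(ValueError, match="self-intersecting"):
            area(bow)

    @settings(max_examples=50, deadline=None)
    @given(
        x=st.floats(-1e3, 1e3, allow_nan=False),
        y=st.floats(-1e3, 1e3, allow_nan=False),
    )
    def test_scalar_sq_diff_properties(self, x, y):
        assert scalar_sq_diff(x, y) == scalar_sq_diff(y, x) == (x - y) ** 2
        assert scalar_sq_diff(x, x) == 0.0


class TestTurningFunction:
    def test_square_steps(self, square):
        tf = turning_function(square)
        # four piecewise-constant levels separated by +90 at quarter arcs
        levels = np.unique(np.round(tf.theta, 6))
        assert len(levels) == 4
        assert np.allclose(np.diff(levels), 90.0)

    def test_total_turning_360(self, shape_pool):
        for shape in list(shape_pool.values())[:10]:
            assert turning_function(shape).total_turning == pytest.approx(
                360.0, abs=1e-6
            )

    def test_scale_invariance(self, small_pool):
        shape = next(iter(small_pool.values()))
        scaled = ShapeOutline(points=shape.points * 3.7)
        a, b = turning_function(shape), turning_function(scaled)
        np.testing.assert_allclose(a.s, b.s, atol=1e-12)
        np.testing.assert_allclose(a.theta, b.theta, atol=1e-9)

    def test_distance_self_zero(self, square):
        assert turning_distance(square, square) < 1e-9

    def test_distance_start_shift_zero(self, square):
        rolled = ShapeOutline(points=np.roll(square.points, -100, axis=0))
        assert turning_distance(square, rolled) < 1e-9

    def test_brute_force_oracle_12gons(self):
        rng = np.random.default_rng(9)
        cfg = MetricConfig(turning_grid=360)
        for _ in range(3):
            a, b = random_polygon(12, rng), random_polygon(12, rng)
            ta = turning_function(a).sample(cfg.turning_grid)
            tb = turning_function(b).sample(cfg.turning_grid)
            assert turning_distance(a, b, cfg) == pytest.approx(
                brute_turning_distance(ta, tb), abs=1e-6
            )

    def test_symmetry(self, small_pool):
        shapes = list(small_pool.values())
        d_ab = turning_distance(shapes[0], shapes[1])
        d_ba = turning_distance(shapes[1], shapes[0])
        assert d_ab == pytest.approx(d_ba, abs=1e-6)


class TestOverlayMetrics:
    def test_iou_identity(self, circle):
        assert intersection_over_union(circle, circle, "actual") == pytest.approx(
            1.0, abs=1e-9
        )

    def test_iou_concentric_circles(self):
        c1 = circle_outline(10.0)
        c2 = circle_outline(20.0)
        assert intersection_over_union(c1, c2, "actual") == pytest.approx(
            0.25, abs=2e-3
        )

    def test_hausdorff_identity(self, circle):
        assert hausdorff_distance(circle, circle, "actual") < 1e-9

    def test_hausdorff_concentric_circles(self):
        c8, c10 = circle_outline(8.0), circle_outline(10.0)
        assert hausdorff_distance(c8, c10, "actual") == pytest.approx(2.0, abs=2e-3)

    def test_iou_matches_brute_force(self, small_pool):
        cfg = MetricConfig()
        shapes = list(small_pool.values())
        rng = np.random.default_rng(3)
        for _ in range(5):
            i, j = rng.choice(len(shapes), 2, replace=False)
            a = ShapeOutline(points=shapes[i].points[::8])
            b = ShapeOutline(points=shapes[j].points[::8])
            got = intersection_over_union(a, b, "actual", cfg)
            from oneback.shapes import area_centroid

            pa = a.points - area_centroid(a.points)
            pb = b.points - area_centroid(b.points)
            assert got == pytest.approx(brute_iou(pa, pb), abs=1e-9)

    def test_hausdorff_matches_brute_force(self, small_pool):
        from oneback.shapes import area_centroid

        shapes = list(small_pool.values())
        rng = np.random.default_rng(4)
        for _ in range(5):
            i, j = rng.choice(len(shapes), 2, replace=False)
            a, b = shapes[i], shapes[j]
            got = hausdorff_distance(a, b, "actual")
            pa = a.points - area_centroid(a.points)
            pb = b.points - area_centroid(b.points)
            assert got == pytest.approx(brute_hausdorff(pa, pb), abs=1e-9)

    def test_optimal_dominance(self, small_pool, fast_config):
        shapes = list(small_pool.values())
        rng = np.random.default_rng(5)
        for _ in range(10):
            i, j = rng.choice(len(shapes), 2, replace=False)
            a = rotate_shape(shapes[i], float(rng.choice([0, 90, 180, 270])))
            b = rotate_shape(shapes[j], float(rng.choice([0, 90, 180, 270])))
            assert intersection_over_union(
                a, b, "optimal", fast_config
            ) >= intersection_over_union(a, b, "actual", fast_config)
            assert hausdorff_distance(
                a, b, "optimal", fast_config
            ) <= hausdorff_distance(a, b, "actual", fast_config)

    def test_bad_mode_errors(self, circle):
        with pytest.raises(ValueError, match="mode"):
            intersection_over_union(circle, circle, "best")
        with pytest.raises(ValueError, match="mode"):
            hausdorff_distance(circle, circle, "best")


class TestDissimilarityTable:
    @pytest.fixture(scope="class")
    def session(self, shape_pool, fast_config):
        rng = np.random.default_rng(21)
        trials = generate_session(sorted(shape_pool), rng)
        table = compute_dissimilarity_table(trials, shape_pool, fast_config, rng)
        return trials, table

    def test_row_count(self, session):
        _, table = session
        assert len(table) == 8 * 71

    def test_match_identity_rows(self, session):
        trials, table = session
        merged = table.merge(trials, on="trial_id")
        same = merged[merged["is_match"] & (merged["orientation_delta"] == 0.0)]
        assert len(same) > 0
        assert np.all(same["hausdorff_actual"] < 1e-9)
        assert np.all(same["iou_actual"] > 1.0 - 1e-9)
        assert np.all(same["turning_distance"] < 1e-9)

    def test_random_u_deterministic(self, shape_pool, fast_config):
        trials = generate_session(sorted(shape_pool), np.random.default_rng(22))
        t1 = compute_dissimilarity_table(
            trials, shape_pool, fast_config, np.random.default_rng(1)
        )
        t2 = compute_dissimilarity_table(
            trials, shape_pool, fast_config, np.random.default_rng(1)
        )
        np.testing.assert_array_equal(t1["random_u"], t2["random_u"])

    def test_dominance_in_table(self, session):
        _, table = session
        assert np.all(table["iou_optimal"] >= table["iou_actual"])
        assert np.all(table["hausdorff_optimal"] <= table["hausdorff_actual"])

    def test_value_ranges(self, session):
        _, table = session
        for col in ("iou_actual", "iou_optimal", "random_u"):
            assert table[col].between(0, 1).all()
        nonneg = [c for c in METRIC_COLUMNS if "iou" not in c and c != "random_u"]
        for col in nonneg:
            assert (table[col] >= 0).all()

    def test_missing_shape_errors(self, shape_pool, fast_config):
        trials = generate_session(sorted(shape_pool), np.random.default_rng(23))
        trials.loc[5, "current_shape_id"] = "ghost"
        with pytest.raises(KeyError, match="ghost"):
            compute_dissimilarity_table(trials, shape_pool, fast_config)

    def test_orientation_invariant_columns(self, shape_pool, fast_config):
        """Rotating presentations must not move orientation-invariant metrics."""
        ids = sorted(shape_pool)[:2]
        rows = []
        for t, (po, co) in enumerate([(0, 0), (0, 90), (90, 180), (270, 90)]):
            rows.append(
                {
                    "trial_id": t,
                    "condition": "VV",
                    "prev_shape_id": ids[0],
                    "current_shape_id": ids[1],
                    "prev_orientation_deg": float(po),
                    "current_orientation_deg": float(co),
                }
            )
        trials = pd.DataFrame(rows)
        table = compute_dissimilarity_table(trials, shape_pool, fast_config)
        invariant = [
            "curvature_cdf_sse",
            "aspect_ratio_sq_diff_optimal",
            "area_sq_diff",
            "hull_area_sq_diff",
            "compactness_sq_diff",
            "turning_distance",
            "iou_optimal",
            "hausdorff_optimal",
        ]
        for col in invariant:
            assert table[col].nunique() == 1, col
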