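"""Per-shape measures and pairwise shape-dissimilarity metrics.

Eight metric families are provided, three of which come in two variants:
``actual`` (evaluated at the presented orientations) and ``optimal``
(evaluated at the relative rotation that maximizes agreement, searched on a
configurable angular grid that always contains the presented offset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, cKDTree
from shapely.geometry import Polygon

from oneback.shapes import (
    ShapeOutline,
    area_centroid,
    rotate_shape,
    signed_area,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MetricConfig",
    "AngleCDF",
    "TurningFunction",
    "METRIC_COLUMNS",
    "VARIANT_PAIRS",
    "local_angle_distribution",
    "curvature_cdf_sse",
    "aspect_ratio",
    "aspect_ratio_dissimilarity",
    "area",
    "hull_area",
    "compactness",
    "scalar_sq_diff",
    "turning_function",
    "turning_distance",
    "intersection_over_union",
    "hausdorff_distance",
    "compute_dissimilarity_table",
]

#: Column order of the dissimilarity table.
METRIC_COLUMNS = [
    "curvature_cdf_sse",
    "aspect_ratio_sq_diff_actual",
    "aspect_ratio_sq_diff_optimal",
    "area_sq_diff",
    "hull_area_sq_diff",
    "compactness_sq_diff",
    "turning_distance",
    "iou_actual",
    "iou_optimal",
    "hausdorff_actual",
    "hausdorff_optimal",
    "random_u",
]

#: (actual, optimal) column pairs for the rotation-variant metrics.
VARIANT_PAIRS = {
    "aspect_ratio_sq_diff": (
        "aspect_ratio_sq_diff_actual",
        "aspect_ratio_sq_diff_optimal",
    ),
    "iou": ("iou_actual", "iou_optimal"),
    "hausdorff": ("hausdorff_actual", "hausdorff_optimal"),
}


@dataclass(frozen=True)
class MetricConfig:
    """Knobs shared by the metric computations.

    ``rotation_step_deg`` sets the granularity of every rotation search
    (aspect ratio and the @optimal IoU/Hausdorff searches).  It must divide
    90 so the search grid contains all presented 90-degree offsets, keeping
    the @optimal-dominance guarantees exact.  ``search_points`` optionally
    subsamples perimeters (evenly) before IoU/Hausdorff computations — both
    variants consistently — to trade accuracy for speed.
    """

    span_points: int = 101
    rotation_step_deg: float = 1.0
    cdf_grid_step_deg: float = 0.5
    search_points: int | None = None
    turning_grid: int = 512

    def __post_init__(self):
        if self.span_points < 3 or self.span_points % 2 == 0:
            raise ValueError("span_points must be odd and >= 3")
        if self.rotation_step_deg <= 0 or 90.0 % self.rotation_step_deg != 0:
            raise ValueError("rotation_step_deg must be positive and divide 90")
        if self.cdf_grid_step_deg <= 0:
            raise ValueError("cdf_grid_step_deg must be positive")

    @property
    def rotation_grid(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.rotation_step_deg)

    @property
    def cdf_grid(self) -> np.ndarray:
        return np.arange(0.0, 360.0 + self.cdf_grid_step_deg, self.cdf_grid_step_deg)


@dataclass(frozen=True)
class AngleCDF:
    """Sorted local-angle samples, evaluable as an empirical CDF on a grid."""

    samples: np.ndarray  # sorted, degrees in (0, 360)
    span_points: int
    grid_step_deg: float

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.samples, grid, side="right") / len(self.samples)


@dataclass(frozen=True)
class TurningFunction:
    """Cumulative tangent angle vs normalized arc length, piecewise constant.

    ``theta[i]`` (degrees) holds on the arc interval ``[s[i], s[i + 1])``;
    ``s`` has length ``len(theta) + 1`` with ``s[0] = 0`` and ``s[-1] = 1``.
    """

    s: np.ndarray
    theta: np.ndarray

    @property
    def total_turning(self) -> float:
        """Accumulated turning over one full traversal (+360 for simple CCW)."""
        closing = np.mod(self.theta[0] - self.theta[-1] + 180.0, 360.0) - 180.0
        return float(self.theta[-1] + closing - self.theta[0])

    def sample(self, n: int) -> np.ndarray:
        """Evaluate at the n midpoints (i + 0.5)/n."""
        mid = (np.arange(n) + 0.5) / n
        idx = np.searchsorted(self.s, mid, side="right") - 1
        return self.theta[np.clip(idx, 0, len(self.theta) - 1)]


# ---------------------------------------------------------------------------
# per-shape measures


def local_angle_distribution(
    shape: ShapeOutline, config: MetricConfig | None = None
) -> AngleCDF:
    """Local angle at every perimeter point over a fixed span.

    For span ``2h + 1`` the angle at point ``p`` is the interior angle
    between the chord vectors ``p -> p-h`` and ``p -> p+h`` (circular
    indexing), measured in degrees in (0, 360): 180 on a straight stretch,
    < 180 where the boundary turns left (convex), > 180 where it turns right.
    """
    config = config or MetricConfig()
    pts = shape.points
    n = len(pts)
    if n <= config.span_points:
        raise ValueError(
            f"span of {config.span_points} points needs more than "
            f"{config.span_points} perimeter points (got {n})"
        )
    h = config.span_points // 2
    back = np.roll(pts, h, axis=0) - pts  # p -> p-h
    fwd = np.roll(pts, -h, axis=0) - pts  # p -> p+h
    ang = np.degrees(
        np.arctan2(back[:, 1], back[:, 0]) - np.arctan2(fwd[:, 1], fwd[:, 0])
    )
    ang = np.mod(ang, 360.0)
    return AngleCDF(
        samples=np.sort(ang),
        span_points=config.span_points,
        grid_step_deg=config.cdf_grid_step_deg,
    )


def curvature_cdf_sse(a: AngleCDF, b: AngleCDF) -> float:
    """Sum of squared differences between two angle CDFs on a fixed grid."""
    if a.span_points != b.span_points or a.grid_step_deg != b.grid_step_deg:
        raise ValueError("AngleCDFs computed with different span/grid settings")
    grid = np.arange(0.0, 360.0 + a.grid_step_deg, a.grid_step_deg)
    diff = a.evaluate(grid) - b.evaluate(grid)
    return float(np.sum(diff * diff))


def _bbox_ratios(points: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """x-span / y-span of the bounding box after rotating by each angle."""
    theta = np.deg2rad(angles_deg)[:, None]
    x, y = points[:, 0], points[:, 1]
    xr = x * np.cos(theta) - y * np.sin(theta)
    yr = x * np.sin(theta) + y * np.cos(theta)
    xspan = xr.max(axis=1) - xr.min(axis=1)
    yspan = yr.max(axis=1) - yr.min(axis=1)
    if np.any(xspan == 0.0) or np.any(yspan == 0.0):
        raise ValueError("degenerate shape with zero bounding-box span")
    return xspan / yspan


def aspect_ratio(shape: ShapeOutline, config: MetricConfig | None = None) -> float:
    """Largest bounding-box x/y ratio over rotations at the configured step.

    Always >= 1: a 90-degree rotation inverts the ratio, and the grid
    contains both angles.
    """
    config = config or MetricConfig()
    return float(_bbox_ratios(shape.points, config.rotation_grid).max())


def aspect_ratio_dissimilarity(
    prev: ShapeOutline,
    curr: ShapeOutline,
    mode: str = "actual",
    config: MetricConfig | None = None,
) -> float:
    """Squared aspect-ratio difference between two shapes.

    ``optimal``: squared difference of the rotation-maximized ratios.
    ``actual``: the previous shape sets the frame — its ratio is measured at
    the angle where it (as presented) attains its maximum, and the current
    shape's bounding-box ratio is measured at that same absolute angle.
    """
    config = config or MetricConfig()
    grid = config.rotation_grid
    if mode == "optimal":
        return scalar_sq_diff(aspect_ratio(prev, config), aspect_ratio(curr, config))
    if mode != "actual":
        raise ValueError(f"mode must be 'actual' or 'optimal', got {mode!r}")
    ratios_prev = _bbox_ratios(prev.points, grid)
    phi_idx = int(np.argmax(ratios_prev))
    r_prev = float(ratios_prev[phi_idx])
    r_curr = float(_bbox_ratios(curr.points, grid[phi_idx : phi_idx + 1])[0])
    return scalar_sq_diff(r_prev, r_curr)


def _check_simple(shape: ShapeOutline):
    if not Polygon(shape.points).is_valid:
        raise ValueError(f"self-intersecting polygon (shape_id={shape.shape_id!r})")


def area(shape: ShapeOutline) -> float:
    """Polygon area (shoelace), mm^2."""
    _check_simple(shape)
    return abs(signed_area(shape.points))


def hull_area(shape: ShapeOutline) -> float:
    """Area of the convex hull of the perimeter points, mm^2."""
    _check_simple(shape)
    return float(ConvexHull(shape.points).volume)


def compactness(shape: ShapeOutline) -> float:
    """Area / convex-hull area; 1 for convex shapes."""
    return area(shape) / hull_area(shape)


def scalar_sq_diff(x: float, y: float) -> float:
    """(x - y)^2."""
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("inputs must be finite")
    return float((x - y) ** 2)


# ---------------------------------------------------------------------------
# turning function / turning distance


def turning_function(shape: ShapeOutline) -> TurningFunction:
    """Cumulative counterclockwise tangent angle vs normalized arc length.

    Total turning over one traversal is +360 degrees.  Clockwise inputs are
    auto-reoriented with a logged warning.
    """
    pts = shape.points
    if signed_area(pts) < 0:
        logger.warning("clockwise polygon auto-reoriented to counterclockwise")
        pts = pts[::-1]
    edges = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    headings = np.degrees(np.arctan2(edges[:, 1], edges[:, 0]))
    turns = np.mod(np.diff(headings) + 180.0, 360.0) - 180.0
    theta = headings[0] + np.concatenate([[0.0], np.cumsum(turns)])
    s = np.concatenate([[0.0], np.cumsum(lengths)]) / lengths.sum()
    s[-1] = 1.0
    return TurningFunction(s=s, theta=theta)


def turning_distance(
    a: ShapeOutline, b: ShapeOutline, config: MetricConfig | None = None
) -> float:
    """L2 distance between turning functions, minimized over start shifts.

    Both functions are sampled on a common uniform arc-length grid.  For each
    circular shift of one function (with the +360 wrap applied past the end)
    the constant angular offset is optimized in closed form (the mean
    difference), leaving the standard deviation of the pointwise difference;
    the minimum over shifts is returned.
    """
    config = config or MetricConfig()
    m = config.turning_grid
    ta = turning_function(a).sample(m)
    tb = turning_function(b).sample(m)
    doubled = np.concatenate([ta, ta + 360.0])
    shifted = np.lib.stride_tricks.sliding_window_view(doubled, m)[:m]
    diff = tb[None, :] - shifted
    var = diff.var(axis=1)
    return float(np.sqrt(var.min()))


# ---------------------------------------------------------------------------
# overlay metrics (IoU, Hausdorff)


def _centered(shape: ShapeOutline, config: MetricConfig) -> np.ndarray:
    pts = shape.points - area_centroid(shape.points)
    k = config.search_points
    if k is not None and k < len(pts):
        idx = (np.arange(k) * len(pts)) // k
        pts = pts[idx]
    return pts


def _rotated(points: np.ndarray, angle_deg: float) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return points @ np.array([[c, s], [-s, c]])


def _iou(pa: Polygon, pb: Polygon) -> float:
    inter = pa.intersection(pb).area
    if inter == 0.0:
        return 0.0
    return min(1.0, inter / (pa.area + pb.area - inter))


def intersection_over_union(
    a: ShapeOutline,
    b: ShapeOutline,
    mode: str = "actual",
    config: MetricConfig | None = None,
) -> float:
    """Area IoU of the two shapes overlaid with aligned area centroids.

    ``actual`` uses the presented orientations; ``optimal`` maximizes over
    rotations of ``b`` on the configured grid (which includes 0, i.e. the
    presented configuration, so optimal >= actual).
    """
    config = config or MetricConfig()
    pa = Polygon(_centered(a, config))
    pb_pts = _centered(b, config)
    if pa.area == 0.0 or abs(signed_area(pb_pts)) == 0.0:
        raise ValueError("degenerate zero-area shape")
    if mode == "actual":
        return _iou(pa, Polygon(pb_pts))
    if mode != "optimal":
        raise ValueError(f"mode must be 'actual' or 'optimal', got {mode!r}")
    best = 0.0
    for ang in config.rotation_grid:
        best = max(best, _iou(pa, Polygon(_rotated(pb_pts, ang))))
    return best


def _sym_hausdorff(tree_a: cKDTree, tree_b: cKDTree, pa, pb) -> float:
    d_ab = tree_b.query(pa)[0].max()
    d_ba = tree_a.query(pb)[0].max()
    return float(max(d_ab, d_ba))


def hausdorff_distance(
    a: ShapeOutline,
    b: ShapeOutline,
    mode: str = "actual",
    config: MetricConfig | None = None,
) -> float:
    """Symmetric Hausdorff distance (mm) after centroid alignment.

    ``optimal`` minimizes over rotations of ``b`` on the configured grid
    (which includes the presented configuration, so optimal <= actual).
    """
    config = config or MetricConfig()
    pa = _centered(a, config)
    pb = _centered(b, config)
    tree_a, tree_b = cKDTree(pa), cKDTree(pb)
    if mode == "actual":
        return _sym_hausdorff(tree_a, tree_b, pa, pb)
    if mode != "optimal":
        raise ValueError(f"mode must be 'actual' or 'optimal', got {mode!r}")
    best = np.inf
    for ang in config.rotation_grid:
        # hausdorff(a, R b): query b's tree with R^-1 a and a's tree with R b
        rb = _rotated(pb, ang)
        ra_inv = _rotated(pa, -ang)
        d = max(tree_b.query(ra_inv)[0].max(), tree_a.query(rb)[0].max())
        best = min(best, d)
    return float(best)


# ---------------------------------------------------------------------------
# per-trial dissimilarity table


class _PairCache:
    """Memoized per-shape and per-pair quantities for table computation.

    Shapes are held at canonical orientation; orientation-dependent values
    are derived from the relative presented offset, which for the overlay
    metrics fully determines the @actual value and leaves the @optimal value
    pair-invariant (the search grid contains all 90-degree offsets).
    """

    def __init__(self, shapes: dict[str, ShapeOutline], config: MetricConfig):
        self.shapes = shapes
        self.config = config
        self._shape: dict[str, dict] = {}
        self._pair: dict = {}
        self._pair_delta: dict = {}

    def shape_stats(self, sid: str) -> dict:
        if sid not in self._shape:
            s = self.shapes[sid]
            ratios = _bbox_ratios(s.points, self.config.rotation_grid)
            self._shape[sid] = {
                "cdf": local_angle_distribution(s, self.config),
                "ratios": ratios,
                "ar": float(ratios.max()),
                "ar_argmax": int(np.argmax(ratios)),
                "area": area(s),
                "hull_area": hull_area(s),
                "turning": turning_function(s).sample(self.config.turning_grid),
                "centered": _centered(s, self.config),
            }
            st = self._shape[sid]
            st["compactness"] = st["area"] / st["hull_area"]
        return self._shape[sid]

    def pair_stats(self, sa: str, sb: str) -> dict:
        key = (sa, sb) if sa <= sb else (sb, sa)
        if key not in self._pair:
            a, b = self.shape_stats(key[0]), self.shape_stats(key[1])
            m = self.config.turning_grid
            doubled = np.concatenate([a["turning"], a["turning"] + 360.0])
            shifted = np.lib.stride_tricks.sliding_window_view(doubled, m)[:m]
            tdist = float(np.sqrt((b["turning"][None, :] - shifted).var(axis=1).min()))
            pa_poly = Polygon(a["centered"])
            tree_a, tree_b = cKDTree(a["centered"]), cKDTree(b["centered"])
            iou_by_delta, haus_by_delta = {}, {}
            iou_best, haus_best = 0.0, np.inf
            for ang in self.config.rotation_grid:
                rb = _rotated(b["centered"], ang)
                i = _iou(pa_poly, Polygon(rb))
                h = max(
                    tree_b.query(_rotated(a["centered"], -ang))[0].max(),
                    tree_a.query(rb)[0].max(),
                )
                iou_best, haus_best = max(iou_best, i), min(haus_best, h)
                if ang % 90.0 == 0.0:
                    iou_by_delta[ang], haus_by_delta[ang] = i, float(h)
            self._pair[key] = {
                "turning_distance": tdist,
                "curvature_cdf_sse": curvature_cdf_sse(a["cdf"], b["cdf"]),
                "iou_optimal": iou_best,
                "hausdorff_optimal": float(haus_best),
                "iou_by_delta": iou_by_delta,
                "hausdorff_by_delta": haus_by_delta,
            }
        return self._pair[key]

    def actual_overlay(self, prev: str, curr: str, delta: float) -> tuple[float, float]:
        """(iou_actual, hausdorff_actual) for curr rotated ``delta`` past prev."""
        key = (prev, curr) if prev <= curr else (curr, prev)
        stats = self.pair_stats(prev, curr)
        # cached deltas rotate the lexicographically larger shape; flip sign
        # when the roles are swapped (both metrics are symmetric)
        eff = delta % 360.0 if key == (prev, curr) else (-delta) % 360.0
        if eff in stats["iou_by_delta"]:
            return stats["iou_by_delta"][eff], stats["hausdorff_by_delta"][eff]
        a, b = self.shape_stats(key[0]), self.shape_stats(key[1])
        rb = _rotated(b["centered"], eff)
        i = _iou(Polygon(a["centered"]), Polygon(rb))
        h = _sym_hausdorff(
            cKDTree(a["centered"]), cKDTree(rb), a["centered"], rb
        )
        return i, h

    def aspect_actual(self, prev: str, curr: str, delta: float) -> float:
        a, b = self.shape_stats(prev), self.shape_stats(curr)
        grid = self.config.rotation_grid
        # previous shape's max-ratio frame, carried to the current shape:
        # ratio(curr0, phi_max(prev0) + delta)
        shift = int(round(delta / self.config.rotation_step_deg))
        idx = (a["ar_argmax"] + shift) % len(grid)
        return scalar_sq_diff(a["ar"], float(b["ratios"][idx]))


def compute_dissimilarity_table(
    trials: pd.DataFrame,
    shapes: dict[str, ShapeOutline],
    config: MetricConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """One row of all metric columns per analyzable (non-block-initial) trial.

    ``shapes`` maps shape_id to the canonical (orientation 0) outline; the
    trial table supplies presented orientations.  ``random_u`` is drawn once
    per trial from U(0, 1) with the provided generator/seed.
    """
    config = config or MetricConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    cache = _PairCache(shapes, config)
    usable = trials[trials["prev_shape_id"].notna() & (trials["condition"] != "warmup")]
    missing = set(usable["current_shape_id"]) | set(usable["prev_shape_id"])
    missing -= set(shapes)
    if missing:
        bad = usable[
            usable["current_shape_id"].isin(missing)
            | usable["prev_shape_id"].isin(missing)
        ].iloc[0]
        raise KeyError(
            f"trial {bad['trial_id']} references unknown shape(s): {sorted(missing)}"
        )
    rows = []
    for t in usable.itertuples(index=False):
        prev, curr = t.prev_shape_id, t.current_shape_id
        delta = (t.current_orientation_deg - t.prev_orientation_deg) % 360.0
        a, b = cache.shape_stats(prev), cache.shape_stats(curr)
        pair = cache.pair_stats(prev, curr)
        iou_act, haus_act = cache.actual_overlay(prev, curr, delta)
        rows.append(
            {
                "trial_id": t.trial_id,
                "curvature_cdf_sse": pair["curvature_cdf_sse"],
                "aspect_ratio_sq_diff_actual": cache.aspect_actual(prev, curr, delta),
                "aspect_ratio_sq_diff_optimal": scalar_sq_diff(a["ar"], b["ar"]),
                "area_sq_diff": scalar_sq_diff(a["area"], b["area"]),
                "hull_area_sq_diff": scalar_sq_diff(a["hull_area"], b["hull_area"]),
                "compactness_sq_diff": scalar_sq_diff(
                    a["compactness"], b["compactness"]
                ),
                "turning_distance": pair["turning_distance"],
                "iou_actual": iou_act,
                "iou_optimal": pair["iou_optimal"],
                "hausdorff_actual": haus_act,
                "hausdorff_optimal": pair["hausdorff_optimal"],
                "random_u": rng.uniform(),
            }
        )
    return pd.DataFrame(rows, columns=["trial_id"] + METRIC_COLUMNS)
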