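"""Random blob-union shape generation and perimeter canonicalization.

Shapes are built by overlaying two or three smooth "blobs" (periodic cubic
splines through random control points) and taking the filled union.  Accepted
shapes are scaled to a fixed maximum extent and resampled to a closed,
counterclockwise perimeter point list with uniform arc-length spacing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "ClosedCurve",
    "ShapeOutline",
    "GeneratorConfig",
    "GenerationError",
    "generate_blob",
    "generate_shape",
    "generate_stimulus_set",
    "resample_perimeter",
    "rotate_shape",
    "blob_union",
    "signed_area",
    "area_centroid",
    "perimeter_length",
    "max_extent",
]


class GenerationError(RuntimeError):
    """Raised when rejection sampling exhausts its retry budget."""

    def __init__(self, message: str, seed: int | None = None):
        super().__init__(message if seed is None else f"{message} (seed={seed})")
        self.seed = seed


@dataclass(frozen=True)
class ClosedCurve:
    """An ordered closed curve; closure is implicit (last point != first)."""

    points: np.ndarray  # (N, 2) float, mm

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("ClosedCurve needs an (N>=3, 2) point array")
        seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise ValueError("ClosedCurve has zero-length segments")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class ShapeOutline:
    """Closed perimeter point list at (nominally) uniform spacing.

    Points are ordered counterclockwise; the first point is the perimeter
    point with minimal ``(y, x)``.  ``orientation_deg`` records the presented
    orientation; coordinates are always the presented coordinates.
    """

    points: np.ndarray  # (N, 2) float, mm
    shape_id: str = ""
    orientation_deg: float = 0.0
    max_extent_mm: float = field(default=0.0)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if self.max_extent_mm == 0.0:
            object.__setattr__(self, "max_extent_mm", max_extent(pts))

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def perimeter_mm(self) -> float:
        return perimeter_length(self.points)


@dataclass(frozen=True)
class GeneratorConfig:
    n_blobs: int = 2
    n_control_points: int = 3
    target_extent_mm: float = 25.0
    spacing_mm: float = 0.1
    seed: int = 0
    max_rejections: int = 1000

    def __post_init__(self):
        if self.n_blobs not in (2, 3):
            raise ValueError("n_blobs must be 2 or 3")
        if self.n_control_points < 3:
            raise ValueError("n_control_points must be >= 3")
        if self.target_extent_mm <= 0 or self.spacing_mm <= 0:
            raise ValueError("extent and spacing must be positive")
        if self.max_rejections <= 0:
            raise ValueError("max_rejections must be positive")


# ---------------------------------------------------------------------------
# plain-polygon helpers


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area; positive for counterclockwise order."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def area_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of the polygon bounded by ``points``."""
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0.0:
        raise ValueError("degenerate polygon with zero area")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def perimeter_length(points: np.ndarray) -> float:
    seg = np.diff(np.vstack([points, points[:1]]), axis=0)
    return float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))


def max_extent(points: np.ndarray) -> float:
    """Largest axis-aligned span (max of x-span and y-span)."""
    spans = points.max(axis=0) - points.min(axis=0)
    return float(spans.max())


def _is_simple(points: np.ndarray) -> bool:
    try:
        poly = Polygon(points)
    except Exception:
        return False
    return poly.is_valid and poly.area > 0.0


# ---------------------------------------------------------------------------
# blob generation


def _periodic_spline(control: np.ndarray) -> tuple[CubicSpline, np.ndarray]:
    """Closed cubic spline through control points, chord-length parameterized.

    Returns the spline and its knot parameters (one per control point).
    """
    closed = np.vstack([control, control[:1]])
    chord = np.hypot(*np.diff(closed, axis=0).T)
    if np.any(chord == 0.0):
        raise ValueError("coincident control points")
    t = np.concatenate([[0.0], np.cumsum(chord)])
    return CubicSpline(t, closed, axis=0, bc_type="periodic"), t


def _periodic_spline_curve(control: np.ndarray, n_samples: int = 400) -> np.ndarray:
    spline, t = _periodic_spline(control)
    ts = np.linspace(0.0, t[-1], n_samples, endpoint=False)
    return spline(ts)


def _sample_control_points(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in the unit disc, ordered by angle about their mean."""
    pts = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform(-1.0, 1.0, size=(2 * n, 2))
        keep = cand[np.hypot(cand[:, 0], cand[:, 1]) <= 1.0]
        take = min(len(keep), n - got)
        pts[got : got + take] = keep[:take]
        got += take
    ang = np.arctan2(*(pts - pts.mean(axis=0)).T[::-1])
    return pts[np.argsort(ang)]


def generate_blob(config: GeneratorConfig, rng: np.random.Generator) -> ClosedCurve:
    """One random smooth blob: a simple closed spline through random controls."""
    for _ in range(config.max_rejections):
        control = _sample_control_points(config.n_control_points, rng)
        try:
            dense = _periodic_spline_curve(control)
        except ValueError:
            continue
        if _is_simple(dense):
            return ClosedCurve(points=dense)
    raise GenerationError("could not generate a simple blob", seed=config.seed)


def blob_union(curves: list[ClosedCurve], offsets: np.ndarray) -> Polygon | None:
    """Union of blob interiors; ``None`` unless it is a single filled region.

    Interior holes (possible with three blobs) are discarded: only the outer
    boundary of the union counts.
    """
    polys = []
    for curve, off in zip(curves, offsets):
        poly = Polygon(curve.points + off)
        if not poly.is_valid:
            return None
        polys.append(poly)
    merged = polys[0]
    for p in polys[1:]:
        merged = merged.union(p)
    if merged.geom_type != "Polygon" or merged.is_empty:
        return None
    return Polygon(merged.exterior)  # drop holes


def generate_shape(config: GeneratorConfig, rng: np.random.Generator) -> ShapeOutline:
    """A blob-union outline scaled to the target extent, uniformly resampled.

    Blob centers are offset uniformly inside a disc of radius 0.5 so overlap
    is probable; disconnected unions are rejected and resampled.
    """
    for attempt in range(config.max_rejections):
        curves = [generate_blob(config, rng) for _ in range(config.n_blobs)]
        offsets = _sample_control_points(config.n_blobs, rng) * 0.5
        merged = blob_union(curves, offsets)
        if merged is None:
            logger.debug("rejected disconnected blob union (attempt %d)", attempt)
            continue
        boundary = np.asarray(merged.exterior.coords)[:-1]
        scale = config.target_extent_mm / max_extent(boundary)
        outline = resample_perimeter(
            ClosedCurve(points=boundary * scale), config.spacing_mm
        )
        # exact extent after resampling (resampling can shave extreme points)
        pts = outline.points * (config.target_extent_mm / max_extent(outline.points))
        return ShapeOutline(
            points=_canonicalize(pts),
            shape_id=outline.shape_id,
            orientation_deg=0.0,
            max_extent_mm=max_extent(pts),
        )
    raise GenerationError("could not generate a connected blob union", seed=config.seed)


def generate_stimulus_set(
    n_shapes: int, config: GeneratorConfig
) -> tuple[dict[str, ShapeOutline], list[dict]]:
    """Generate ``n_shapes`` outlines plus a manifest of per-shape metadata.

    The number of blobs per shape alternates pseudorandomly between 2 and 3.
    All randomness derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    shapes: dict[str, ShapeOutline] = {}
    manifest: list[dict] = []
    for i in range(n_shapes):
        n_blobs = int(rng.integers(2, 4))
        cfg = replace(config, n_blobs=n_blobs)
        shape = generate_shape(cfg, rng)
        shape_id = f"shape{i:03d}"
        shape = ShapeOutline(
            points=shape.points,
            shape_id=shape_id,
            orientation_deg=0.0,
            max_extent_mm=shape.max_extent_mm,
        )
        shapes[shape_id] = shape
        manifest.append(
            {
                "shape_id": shape_id,
                "seed": config.seed,
                "n_blobs": n_blobs,
                "perimeter_mm": shape.perimeter_mm,
                "n_points": shape.n_points,
            }
        )
    return shapes, manifest


# ---------------------------------------------------------------------------
# canonical perimeter resampling


def _canonicalize(points: np.ndarray) -> np.ndarray:
    """Roll so the first point has minimal (y, then x)."""
    start = np.lexsort((points[:, 0], points[:, 1]))[0]
    return np.roll(points, -start, axis=0)


def resample_perimeter(curve: ClosedCurve, spacing_mm: float) -> ShapeOutline:
    """Resample a closed curve to N = round(perimeter/spacing) points.

    Points are equally spaced by arc length (actual spacing perimeter/N),
    ordered counterclockwise, starting from the minimal-(y, x) point.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    pts = curve.points
    if signed_area(pts) < 0:
        pts = pts[::-1]
    perimeter = perimeter_length(pts)
    if perimeter < 3 * spacing_mm:
        raise ValueError(
            f"degenerate shape: perimeter {perimeter:.4g} mm < 3 x spacing"
        )
    n_out = int(round(perimeter / spacing_mm))
    # anchor the parameterization at the canonical vertex for determinism
    pts = _canonicalize(pts)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = perimeter * np.arange(n_out) / n_out
    x = np.interp(targets, s, closed[:, 0])
    y = np.interp(targets, s, closed[:, 1])
    out = _canonicalize(np.column_stack([x, y]))
    return ShapeOutline(points=out, max_extent_mm=max_extent(out))


def rotate_shape(shape: ShapeOutline, angle_deg: float) -> ShapeOutline:
    """Rigid rotation about the area centroid; orientation metadata updated."""
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    center = area_centroid(shape.points)
    rel = shape.points - center
    rot = rel @ np.array([[c, s], [-s, c]])  # row-vector CCW rotation
    return ShapeOutline(
        points=rot + center,
        shape_id=shape.shape_id,
        orientation_deg=(shape.orientation_deg + angle_deg) % 360.0,
        max_extent_mm=shape.max_extent_mm,
    )
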