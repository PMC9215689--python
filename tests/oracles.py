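"""Independent brute-force oracles used to cross-check the metric
implementations.  These deliberately avoid the code paths (shapely clipping,
KD-trees, vectorized shift search) used by the package."""

import numpy as np
from scipy.spatial.distance import cdist


def brute_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff via the full pairwise distance matrix."""
    d = cdist(a, b)
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def brute_segment_self_intersections(points: np.ndarray) -> int:
    """Count proper crossings between non-adjacent edges of a closed polyline."""
    n = len(points)
    p = points
    q = np.roll(points, -1, axis=0)
    count = 0
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            if _segments_cross(p[i], q[i], p[j], q[j]):
                count += 1
    return count


def _segments_cross(a0, a1, b0, b1) -> bool:
    def orient(p, q, r):
        return (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])

    d1 = orient(a0, a1, b0)
    d2 = orient(a0, a1, b1)
    d3 = orient(b0, b1, a0)
    d4 = orient(b0, b1, a1)
    return (d1 * d2 < 0) and (d3 * d4 < 0)


def _vertical_intervals(poly: np.ndarray, x: float) -> np.ndarray:
    """Sorted y-intervals where the vertical line at x is inside the polygon."""
    x0, y0 = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    mask = ((x0 < x) & (x1 > x)) | ((x0 > x) & (x1 < x))
    t = (x - x0[mask]) / (x1[mask] - x0[mask])
    ys = np.sort(y0[mask] + t * (y1[mask] - y0[mask]))
    if len(ys) % 2:  # grazing a vertex; treat as no contribution
        return np.empty((0, 2))
    return ys.reshape(-1, 2)


def _interval_overlap(ia: np.ndarray, ib: np.ndarray) -> float:
    total = 0.0
    for lo_a, hi_a in ia:
        for lo_b, hi_b in ib:
            total += max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
    return total


def _edge_crossing_xs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x-coordinates of all intersections between edges of a and edges of b."""
    a0 = a
    a1 = np.roll(a, -1, axis=0)
    b0 = b
    b1 = np.roll(b, -1, axis=0)
    da = a1 - a0
    db = b1 - b0
    xs = []
    for i in range(len(a)):
        denom = da[i, 0] * db[:, 1] - da[i, 1] * db[:, 0]
        ok = denom != 0.0
        diff = b0 - a0[i]
        t = (diff[:, 0] * db[:, 1] - diff[:, 1] * db[:, 0])
        u = (diff[:, 0] * da[i, 1] - diff[:, 1] * da[i, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(ok, t / denom, np.nan)
            u = np.where(ok, u / denom, np.nan)
        hit = ok & (t >= 0) & (t <= 1) & (u >= 0) & (u <= 1)
        xs.extend(a0[i, 0] + t[hit] * da[i, 0])
    return np.asarray(xs)


def brute_intersection_area(a: np.ndarray, b: np.ndarray) -> float:
    """Exact polygon-intersection area by vertical scanline integration.

    Between consecutive event abscissae (all vertex x's plus all edge-edge
    crossing x's) both polygons' vertical cross-sections are linear in x, so
    the overlap length is linear and the midpoint value integrates exactly.
    """
    xs = np.concatenate([a[:, 0], b[:, 0], _edge_crossing_xs(a, b)])
    xs = np.unique(xs)
    total = 0.0
    for x1, x2 in zip(xs[:-1], xs[1:]):
        w = x2 - x1
        if w <= 0.0:
            continue
        xm = 0.5 * (x1 + x2)
        total += w * _interval_overlap(
            _vertical_intervals(a, xm), _vertical_intervals(b, xm)
        )
    return total


def brute_iou(a: np.ndarray, b: np.ndarray) -> float:
    def shoelace(p):
        x, y = p[:, 0], p[:, 1]
        return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    inter = brute_intersection_area(a, b)
    union = shoelace(a) + shoelace(b) - inter
    return inter / union


def brute_turning_distance(ta: np.ndarray, tb: np.ndarray) -> float:
    """Explicit double loop over circular start shifts of ta (grid samples)."""
    m = len(ta)
    best = np.inf
    for k in range(m):
        shifted = np.empty(m)
        for i in range(m):
            j = i + k
            shifted[i] = ta[j] if j < m else ta[j - m] + 360.0
        diff = tb - shifted
        offset = diff.mean()
        d = np.sqrt(np.mean((diff - offset) ** 2))
        best = min(best, d)
    return best


def brute_cdf_sse(samples_a, samples_b, grid) -> float:
    total = 0.0
    for g in grid:
        fa = np.sum(samples_a <= g) / len(samples_a)
        fb = np.sum(samples_b <= g) / len(samples_b)
        total += (fa - fb) ** 2
    return total
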