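"""Touchpad partitioning, Monte Carlo random-touch baseline, and
curvature-enrichment analysis of touch sequences.

A sampled finger-center point counts as a touch when it lies outside the
shape with its distance to the perimeter inside ``[rigid_radius,
finger_radius]``; every pad at least partially within ``finger_radius`` of
the point is credited, and credit vectors are normalized to ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from shapely import contains_xy
from shapely.geometry import Polygon

from oneback.metrics import MetricConfig, local_angle_distribution
from oneback.shapes import ShapeOutline

logger = logging.getLogger(__name__)

__all__ = [
    "N_PADS",
    "PadPartition",
    "TouchMCParams",
    "PadModel",
    "partition_pads",
    "touch_mask",
    "monte_carlo_baseline",
    "pad_curvature_scores",
    "build_pad_model",
    "touch_enrichment",
]

N_PADS = 6


@dataclass(frozen=True)
class PadPartition:
    """Six contiguous equal-arc-length perimeter intervals.

    ``edges`` are the seven arc-length breakpoints (0 .. perimeter);
    ``point_pads[i]`` is the pad index of perimeter point ``i``.
    """

    shape_id: str
    edges: np.ndarray
    point_pads: np.ndarray

    def __post_init__(self):
        if len(self.edges) != N_PADS + 1:
            raise ValueError("partition must have exactly six intervals")


@dataclass(frozen=True)
class TouchMCParams:
    n_samples: int = 100_000
    finger_radius_mm: float = 6.0
    rigid_radius_mm: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if not self.rigid_radius_mm < self.finger_radius_mm:
            raise ValueError("rigid_radius must be smaller than finger_radius")
        if self.n_samples < 10_000:
            raise ValueError("n_samples must be at least 10,000")


@dataclass(frozen=True)
class PadModel:
    """Everything the touch analyses need to know about one shape's pads."""

    shape_id: str
    partition: PadPartition
    baseline_ratios: np.ndarray
    curvature_scores: np.ndarray

    @property
    def curvature_norm(self) -> np.ndarray:
        """Scores min-max normalized to [0, 1] (constant scores map to 0)."""
        lo, hi = self.curvature_scores.min(), self.curvature_scores.max()
        if hi == lo:
            return np.zeros(N_PADS)
        return (self.curvature_scores - lo) / (hi - lo)


def partition_pads(shape: ShapeOutline) -> PadPartition:
    """Divide the perimeter into six equal-arc-length pads from the start.

    Perimeter points are uniformly spaced, so the split is by point index;
    the partition is invariant under rigid rotation of the whole shape.
    """
    n = shape.n_points
    perimeter = shape.perimeter_mm
    edges = perimeter * np.arange(N_PADS + 1) / N_PADS
    point_pads = (np.arange(n) * N_PADS) // n
    return PadPartition(shape_id=shape.shape_id, edges=edges, point_pads=point_pads)


def touch_mask(
    shape: ShapeOutline, samples: np.ndarray, params: TouchMCParams
) -> np.ndarray:
    """True where a candidate finger-center point counts as a touch.

    A touch is outside the shape with perimeter distance in
    ``[rigid_radius, finger_radius]``.
    """
    outside = ~contains_xy(Polygon(shape.points), samples[:, 0], samples[:, 1])
    dist = cKDTree(shape.points).query(samples)[0]
    return (
        outside
        & (dist >= params.rigid_radius_mm)
        & (dist <= params.finger_radius_mm)
    )


def monte_carlo_baseline(
    shape: ShapeOutline,
    pads: PadPartition,
    params: TouchMCParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-pad baseline touch ratios from uniform random finger placements.

    Candidate points are sampled uniformly in the shape's bounding box padded
    by ``finger_radius`` on all sides.  Returns six ratios summing to one.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    pts = shape.points
    pad = params.finger_radius_mm
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    samples = rng.uniform(lo, hi, size=(params.n_samples, 2))
    touch_pts = samples[touch_mask(shape, samples, params)]
    if len(touch_pts) == 0:
        raise RuntimeError("Monte Carlo produced zero touches (degenerate geometry)")

    credits = np.zeros(N_PADS)
    for k in range(N_PADS):
        pad_tree = cKDTree(pts[pads.point_pads == k])
        d = pad_tree.query(touch_pts)[0]
        credits[k] = np.count_nonzero(d <= params.finger_radius_mm)
    return credits / credits.sum()


def pad_curvature_scores(
    shape: ShapeOutline,
    pads: PadPartition,
    config: MetricConfig | None = None,
) -> np.ndarray:
    """Per-pad curvature: mean |local angle - 180| over the pad's points."""
    config = config or MetricConfig()
    pts = shape.points
    n = len(pts)
    h = config.span_points // 2
    back = np.roll(pts, h, axis=0) - pts
    fwd = np.roll(pts, -h, axis=0) - pts
    ang = np.mod(
        np.degrees(
            np.arctan2(back[:, 1], back[:, 0]) - np.arctan2(fwd[:, 1], fwd[:, 0])
        ),
        360.0,
    )
    dev = np.abs(ang - 180.0)
    return np.array([dev[pads.point_pads == k].mean() for k in range(N_PADS)])


def build_pad_model(
    shape: ShapeOutline,
    params: TouchMCParams | None = None,
    rng: np.random.Generator | None = None,
    config: MetricConfig | None = None,
) -> PadModel:
    """Partition + Monte Carlo baseline + curvature scores for one shape."""
    params = params or TouchMCParams()
    pads = partition_pads(shape)
    return PadModel(
        shape_id=shape.shape_id,
        partition=pads,
        baseline_ratios=monte_carlo_baseline(shape, pads, params, rng),
        curvature_scores=pad_curvature_scores(shape, pads, config),
    )


def touch_enrichment(
    touches: pd.DataFrame,
    trials: pd.DataFrame,
    pad_models: dict[str, PadModel],
    weight: str = "duration",
) -> tuple[pd.DataFrame, float, float]:
    """Observed/baseline enrichment per (shape, pad) and its curvature link.

    Observed ratios aggregate touch ``duration_ms`` (or counts with
    ``weight='count'``) per pad over all trials of each shape.  Enrichment
    above 1 means a pad was touched more than the random-touch baseline
    predicts; the returned Pearson r correlates pad curvature with
    enrichment across all pads of all touched shapes, so a positive r means
    high-curvature regions attract touches.

    Returns ``(stats_frame, r, p_value)``.
    """
    if touches.empty:
        raise ValueError("no touches supplied")
    if weight not in ("duration", "count"):
        raise ValueError("weight must be 'duration' or 'count'")
    merged = touches.merge(
        trials[["trial_id", "current_shape_id"]], on="trial_id", how="left"
    )
    if merged["current_shape_id"].isna().any():
        raise KeyError("touch rows reference trial_ids absent from the trial table")
    merged["w"] = merged["duration_ms"] if weight == "duration" else 1.0

    rows = []
    for sid, grp in merged.groupby("current_shape_id"):
        model = pad_models[sid]
        observed = np.zeros(N_PADS)
        sums = grp.groupby("pad_index")["w"].sum()
        observed[sums.index.to_numpy()] = sums.to_numpy()
        observed = observed / observed.sum()
        baseline = np.asarray(model.baseline_ratios)
        for k in range(N_PADS):
            if baseline[k] == 0.0:
                warnings.warn(
                    f"pad {k} of {sid} has zero baseline ratio; excluded",
                    stacklevel=2,
                )
                continue
            rows.append(
                {
                    "shape_id": sid,
                    "pad_index": k,
                    "baseline_ratio": baseline[k],
                    "observed_ratio": observed[k],
                    "curvature_score": float(model.curvature_scores[k]),
                    "enrichment": observed[k] / baseline[k],
                }
            )
    frame = pd.DataFrame(rows)
    r, p = stats.pearsonr(frame["curvature_score"], frame["enrichment"])
    return frame, float(r), float(p)
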