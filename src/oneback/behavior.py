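"""One-back session generation and synthetic observers.

A session is eight 72-trial blocks (two visual-only, two haptic-only, four
alternating, in permuted order).  Each block draws 48 unique shapes from the
pool: the block-initial trial introduces the first shape, every "different"
trial introduces a fresh shape, and every "same" trial repeats the previous
shape, so 24 same trials per block are forced by the 48-shape budget.

The synthetic observer answers "different" with probability
``(1 - eps) * logistic(b0 + sum_k b_k * d_k) + eps / 2`` where the ``d_k``
are (scale-normalized) dissimilarity columns chosen per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oneback.metrics import METRIC_COLUMNS, VARIANT_PAIRS

__all__ = [
    "ObserverParams",
    "BLOCK_TYPES",
    "TRIALS_PER_BLOCK",
    "MATCH_PER_BLOCK",
    "SHAPES_PER_BLOCK",
    "generate_block",
    "generate_session",
    "simulate_observer",
    "simulate_touch_sequences",
]

BLOCK_TYPES = ("visual_only", "haptic_only", "alternating")
TRIALS_PER_BLOCK = 72
MATCH_PER_BLOCK = 24
SHAPES_PER_BLOCK = 48
ORIENTATIONS = np.array([0.0, 90.0, 180.0, 270.0])

TRIAL_COLUMNS = [
    "trial_id",
    "block_id",
    "block_type",
    "condition",
    "nominal_condition",
    "current_shape_id",
    "prev_shape_id",
    "current_orientation_deg",
    "prev_orientation_deg",
    "current_modality",
    "is_match",
    "orientation_delta",
    "response",
    "rt_ms",
]


@dataclass(frozen=True)
class ObserverParams:
    """Logistic choice model with lapse for the synthetic observer.

    ``weights`` maps metric names to slopes.  Keys may be full column names
    (e.g. ``hausdorff_actual``) or variant bases (``iou``, ``hausdorff``,
    ``aspect_ratio_sq_diff``), which are resolved per condition through
    ``mode_per_condition`` (default "actual" everywhere).  Dissimilarity
    columns are divided by their table-wide standard deviation before the
    weights apply, so weights are scale-free; zeros stay zero.
    """

    intercept: float = 0.0
    weights: dict[str, float] = field(default_factory=dict)
    lapse: float = 0.0
    mode_per_condition: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")
        for mode in self.mode_per_condition.values():
            if mode not in ("actual", "optimal"):
                raise ValueError(f"unknown metric variant {mode!r}")

    def resolve_columns(self, condition: str) -> dict[str, float]:
        """Weights keyed by concrete table columns for one condition."""
        mode = self.mode_per_condition.get(condition, "actual")
        resolved = {}
        for name, w in self.weights.items():
            if name in VARIANT_PAIRS:
                actual, optimal = VARIANT_PAIRS[name]
                resolved[actual if mode == "actual" else optimal] = w
            elif name in METRIC_COLUMNS:
                resolved[name] = w
            else:
                raise KeyError(f"unknown metric column or base {name!r}")
        return resolved


def _match_deltas(rng: np.random.Generator) -> np.ndarray:
    """24 orientation deltas in a 1:1:1 ratio of 0 / +-90 / 180, shuffled."""
    third = MATCH_PER_BLOCK // 3
    ninety = np.where(rng.random(third) < 0.5, 90.0, 270.0)
    deltas = np.concatenate([np.zeros(third), ninety, np.full(third, 180.0)])
    return rng.permutation(deltas)


def generate_block(
    block_type: str,
    shape_pool: list[str],
    rng: np.random.Generator,
    block_id: int = 0,
    trial_id_start: int = 0,
) -> pd.DataFrame:
    """One 72-trial block: 24 match trials, 48 unique shapes, 1:1:1 deltas.

    ``shape_pool`` is a list of shape ids (>= 48).  The block-initial trial
    is labeled ``warmup`` but carries the block's nominal condition for the
    design tally.
    """
    if block_type not in BLOCK_TYPES:
        raise ValueError(f"unknown block_type {block_type!r}")
    if len(shape_pool) < SHAPES_PER_BLOCK:
        raise ValueError(
            f"shape pool has {len(shape_pool)} shapes; need {SHAPES_PER_BLOCK}"
        )
    draw = list(rng.choice(shape_pool, size=SHAPES_PER_BLOCK, replace=False))
    # choose which of trials 1..71 are match trials (trial 0 is the warmup)
    match_pos = rng.choice(np.arange(1, TRIALS_PER_BLOCK), MATCH_PER_BLOCK, False)
    is_match = np.zeros(TRIALS_PER_BLOCK, dtype=bool)
    is_match[match_pos] = True
    deltas = iter(_match_deltas(rng))

    if block_type == "visual_only":
        modality = ["V"] * TRIALS_PER_BLOCK
    elif block_type == "haptic_only":
        modality = ["H"] * TRIALS_PER_BLOCK
    else:
        first = "V" if rng.random() < 0.5 else "H"
        other = "H" if first == "V" else "V"
        modality = [first if t % 2 == 0 else other for t in range(TRIALS_PER_BLOCK)]

    rows = []
    next_new = 0
    prev_shape, prev_orient = None, None
    for t in range(TRIALS_PER_BLOCK):
        if t == 0 or not is_match[t]:
            shape = draw[next_new]
            next_new += 1
            orient = float(rng.choice(ORIENTATIONS))
            delta = np.nan
        else:
            shape = prev_shape
            delta = float(next(deltas))
            orient = (prev_orient + delta) % 360.0
        # the warmup's implied previous modality continues the block pattern
        # (same modality in unimodal blocks, opposite in alternating ones),
        # which is the modality of the block's second trial either way
        prev_mod = modality[t - 1] if t > 0 else modality[1]
        nominal = prev_mod + modality[t]
        rows.append(
            {
                "trial_id": trial_id_start + t,
                "block_id": block_id,
                "block_type": block_type,
                "condition": "warmup" if t == 0 else nominal,
                "nominal_condition": nominal,
                "current_shape_id": shape,
                "prev_shape_id": prev_shape,
                "current_orientation_deg": orient,
                "prev_orientation_deg": prev_orient if t > 0 else np.nan,
                "current_modality": modality[t],
                "is_match": bool(is_match[t]) if t > 0 else False,
                "orientation_delta": np.nan if t == 0 or not is_match[t] else min(
                    delta, 360.0 - delta
                ),
                "response": "none",
                "rt_ms": np.nan,
            }
        )
        prev_shape, prev_orient = shape, orient
    assert next_new == SHAPES_PER_BLOCK
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def generate_session(
    shape_pool: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Eight blocks (2 visual-only, 2 haptic-only, 4 alternating), permuted."""
    order = rng.permutation(
        ["visual_only"] * 2 + ["haptic_only"] * 2 + ["alternating"] * 4
    )
    blocks = []
    for b, btype in enumerate(order):
        blocks.append(
            generate_block(
                str(btype),
                shape_pool,
                rng,
                block_id=b,
                trial_id_start=b * TRIALS_PER_BLOCK,
            )
        )
    return pd.concat(blocks, ignore_index=True)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_observer(
    trials: pd.DataFrame,
    dissim: pd.DataFrame,
    params: ObserverParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Sample same/different responses for every non-warmup trial.

    Returns a copy of ``trials`` with the ``response`` column filled
    ('same'/'different'; warmup trials keep 'none').
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    table = dissim.set_index("trial_id") if "trial_id" in dissim.columns else dissim
    out = trials.copy()
    scales = {
        c: (sd if (sd := float(table[c].std(ddof=0))) > 0 else 1.0)
        for c in table.columns
    }
    analyzable = out[out["condition"] != "warmup"]
    missing = set(analyzable["trial_id"]) - set(table.index)
    if missing:
        raise KeyError(f"no dissimilarity row for trials {sorted(missing)[:5]} ...")
    p_diff = pd.Series(np.nan, index=out.index)
    for cond, sub in analyzable.groupby("condition"):
        weights = params.resolve_columns(str(cond))
        for col in weights:
            if col not in table.columns:
                raise KeyError(f"metric column {col!r} absent from table")
        rows = table.loc[sub["trial_id"]]
        eta = np.full(len(sub), params.intercept)
        for col, w in weights.items():
            eta = eta + w * rows[col].to_numpy() / scales[col]
        p = (1.0 - params.lapse) * _logistic(eta) + params.lapse / 2.0
        p_diff.loc[sub.index] = p
    draw = rng.random(len(out))
    answered = p_diff.notna()
    out.loc[answered, "response"] = np.where(
        draw[answered.to_numpy()] < p_diff[answered], "different", "same"
    )
    return out


def simulate_touch_sequences(
    trials: pd.DataFrame,
    pad_models: dict,
    curvature_gain: float = 0.0,
    rng: np.random.Generator | None = None,
    visits_per_trial: float = 12.0,
    duration_median_ms: float = 300.0,
    duration_sigma: float = 0.5,
) -> pd.DataFrame:
    """Curvature-biased pad-visit sequences for every haptic trial.

    Visit probabilities are proportional to
    ``baseline_ratio * (1 + gain * curvature_norm)`` with per-shape
    curvature scores min-max normalized to [0, 1]; ``gain = 0`` reduces to
    the Monte Carlo baseline.  Durations are log-normal; onsets sequential.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    rows = []
    for t in trials.itertuples(index=False):
        if t.current_modality != "H":
            continue
        model = pad_models[t.current_shape_id]
        c = np.asarray(model.curvature_norm)
        w = np.asarray(model.baseline_ratios) * (1.0 + curvature_gain * c)
        if np.any(w < 0):
            raise ValueError(
                f"curvature_gain={curvature_gain} yields negative visit weights"
            )
        if w.sum() == 0:
            raise ValueError("all visit weights are zero")
        p = w / w.sum()
        n = max(1, int(rng.poisson(visits_per_trial)))
        pads = rng.choice(6, size=n, p=p)
        durations = duration_median_ms * np.exp(rng.normal(0.0, duration_sigma, n))
        onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        for pad, onset, dur in zip(pads, onsets, durations):
            rows.append(
                {
                    "trial_id": t.trial_id,
                    "pad_index": int(pad),
                    "onset_ms": float(onset),
                    "duration_ms": float(dur),
                }
            )
    return pd.DataFrame(rows, columns=["trial_id", "pad_index", "onset_ms", "duration_ms"])
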