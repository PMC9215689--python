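"""Binomial-GLM evaluation of shape-dissimilarity metrics.

Each metric is scored by the AIC of a single-predictor logistic model of the
same/different response; a stored uniform-random column provides the chance
baseline, and a metric counts as predictive when it beats that baseline by
at least 3 AIC units.  Multimetric models are grown by forward stepwise
selection under the same 3-unit rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, pearsonr

from oneback.metrics import METRIC_COLUMNS, VARIANT_PAIRS

__all__ = [
    "ModelFit",
    "AIC_THRESHOLD",
    "fit_binomial_glm",
    "evaluate_metrics",
    "select_multimetric",
    "actual_vs_optimal_contrast",
    "binned_accuracy_curve",
    "behavior_summary",
]

#: Minimum AIC improvement for a metric/predictor to count as meaningful.
AIC_THRESHOLD = 3.0


@dataclass(frozen=True)
class ModelFit:
    metric_names: list[str]
    coefficients: np.ndarray  # intercept first
    log_likelihood: float
    n_params: int
    n_obs: int
    converged: bool = True
    std_errors: np.ndarray | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.log_likelihood


def _as_binary(responses: pd.Series | np.ndarray) -> np.ndarray:
    y = np.asarray(responses)
    if y.dtype.kind in "OU":
        bad = ~np.isin(y, ["same", "different"])
        if bad.any():
            raise ValueError(f"unanswered/unknown responses present: {set(y[bad])}")
        y = (y == "different").astype(float)
    return y.astype(float)


def fit_binomial_glm(
    responses: pd.Series | np.ndarray,
    predictors: pd.DataFrame,
) -> ModelFit:
    """Maximum-likelihood logistic fit of responses on standardized predictors.

    Predictors are z-scored (zero mean, unit variance) before fitting, so the
    resulting AIC is invariant to affine rescaling of any column.  Complete
    separation is flagged via ``converged=False`` rather than raised.
    """
    y = _as_binary(responses)
    names = list(predictors.columns)
    if len(y) < 10 * (1 + len(names)):
        warnings.warn(
            f"only {len(y)} observations for {1 + len(names)} parameters",
            stacklevel=2,
        )
    X = np.ones((len(y), 1 + len(names)))
    for j, name in enumerate(names):
        col = predictors[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"predictor {name!r} contains non-finite values")
        sd = col.std()
        if sd == 0.0:
            raise ValueError(f"predictor {name!r} is constant")
        X[:, 1 + j] = (col - col.mean()) / sd
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit(tol=1e-8, maxiter=200)
            llf = float(res.llf)
            bse = np.asarray(res.bse)
            separated = any(
                "PerfectSeparation" in type(w.message).__name__ for w in caught
            )
            # runaway coefficients also signal (quasi-)complete separation
            converged = (
                bool(res.converged)
                and not separated
                and not np.any(np.abs(res.params) > 1e3)
            )
        except Exception:
            # perfect separation or similar degeneracy: refit with a tiny
            # ridge so a (flagged) likelihood is still reported
            res = model.fit_regularized(alpha=1e-6, L1_wt=0.0)
            converged = False
            bse = None
            mu = 1.0 / (1.0 + np.exp(-(X @ np.asarray(res.params))))
            mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
            llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    params = np.asarray(res.params)
    return ModelFit(
        metric_names=names,
        coefficients=params,
        log_likelihood=llf,
        n_params=1 + len(names),
        n_obs=len(y),
        converged=converged,
        std_errors=bse,
    )


def _aligned(
    dissim: pd.DataFrame,
    responses: pd.Series,
    condition: str | None,
    conditions: pd.Series | None,
) -> tuple[pd.DataFrame, pd.Series]:
    table = dissim.set_index("trial_id") if "trial_id" in dissim.columns else dissim
    resp = responses.reindex(table.index).dropna()
    resp = resp[resp != "none"]
    if condition is not None:
        if conditions is None:
            raise ValueError("condition filtering needs a conditions Series")
        keep = conditions.reindex(resp.index) == condition
        resp = resp[keep.fillna(False)]
    if len(resp) < 50:
        warnings.warn(f"only {len(resp)} usable trials", stacklevel=3)
    return table.loc[resp.index], resp


def evaluate_metrics(
    dissim: pd.DataFrame,
    responses: pd.Series,
    condition: str | None = None,
    conditions: pd.Series | None = None,
    metric_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Rank metric columns by single-predictor GLM AIC against chance.

    ``responses`` and ``conditions`` are indexed by trial_id; warmup /
    unanswered trials are dropped.  Returns a frame sorted by AIC ascending
    (ties broken by metric name) with ``delta_aic_vs_random``,
    ``delta_aic_vs_best`` and the ``predictive_flag`` (random AIC beaten by
    at least 3 units).
    """
    table, resp = _aligned(dissim, responses, condition, conditions)
    cols = metric_columns or [c for c in METRIC_COLUMNS if c != "random_u"]
    fits = {}
    for col in cols + ["random_u"]:
        fits[col] = fit_binomial_glm(resp, table[[col]])
    random_aic = fits["random_u"].aic
    rows = [
        {
            "metric": col,
            "aic": fits[col].aic,
            "log_likelihood": fits[col].log_likelihood,
            "converged": fits[col].converged,
        }
        for col in fits
    ]
    frame = pd.DataFrame(rows).sort_values(["aic", "metric"]).reset_index(drop=True)
    frame["delta_aic_vs_random"] = frame["aic"] - random_aic
    frame["delta_aic_vs_best"] = frame["aic"] - frame["aic"].iloc[0]
    frame["predictive_flag"] = (random_aic - frame["aic"]) >= AIC_THRESHOLD
    return frame


def select_multimetric(
    dissim: pd.DataFrame,
    responses: pd.Series,
    candidates: list[str],
    condition: str | None = None,
    conditions: pd.Series | None = None,
) -> tuple[list[str], ModelFit]:
    """Forward stepwise AIC selection starting from the best single metric.

    At each step the candidate yielding the largest AIC decrease is added;
    selection stops when no addition improves AIC by at least 3 units.
    """
    table, resp = _aligned(dissim, responses, condition, conditions)
    unknown = set(candidates) - set(table.columns)
    if unknown:
        raise KeyError(f"unknown candidate columns: {sorted(unknown)}")
    singles = {c: fit_binomial_glm(resp, table[[c]]) for c in candidates}
    chosen = min(singles, key=lambda c: (singles[c].aic, c))
    best_fit = singles[chosen]
    selected = [chosen]
    remaining = [c for c in candidates if c != chosen]
    while remaining:
        trial_fits = {
            c: fit_binomial_glm(resp, table[selected + [c]]) for c in remaining
        }
        addition = min(trial_fits, key=lambda c: (trial_fits[c].aic, c))
        if best_fit.aic - trial_fits[addition].aic < AIC_THRESHOLD:
            break
        selected.append(addition)
        best_fit = trial_fits[addition]
        remaining.remove(addition)
    return selected, best_fit


def actual_vs_optimal_contrast(
    dissim: pd.DataFrame,
    responses: pd.Series,
    condition: str | None = None,
    conditions: pd.Series | None = None,
) -> pd.DataFrame:
    """AIC(@optimal) - AIC(@actual) for each paired rotation-variant metric.

    Positive values mean the @actual variant predicted choices better.
    """
    table, resp = _aligned(dissim, responses, condition, conditions)
    rows = []
    for base, (act, opt) in VARIANT_PAIRS.items():
        aic_act = fit_binomial_glm(resp, table[[act]]).aic
        aic_opt = fit_binomial_glm(resp, table[[opt]]).aic
        rows.append(
            {
                "metric": base,
                "aic_actual": aic_act,
                "aic_optimal": aic_opt,
                "aic_optimal_minus_actual": aic_opt - aic_act,
            }
        )
    return pd.DataFrame(rows)


def binned_accuracy_curve(
    dissim: pd.DataFrame,
    responses: pd.Series,
    metric: str,
    n_bins: int = 10,
) -> dict:
    """Accuracy on nonmatch trials vs binned dissimilarity.

    Callers supply nonmatch trials only (a correct response is 'different').
    The metric is split into ``n_bins`` equal-count bins; returns bin centers
    (mean metric value), per-bin proportion correct, and the Pearson
    correlation between the two.  A constant metric yields ``r = nan`` with
    ``degenerate = True``.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    table = dissim.set_index("trial_id") if "trial_id" in dissim.columns else dissim
    resp = responses.reindex(table.index).dropna()
    resp = resp[resp != "none"]
    values = table.loc[resp.index, metric].to_numpy(dtype=float)
    correct = (np.asarray(resp) == "different").astype(float)
    if np.all(values == values[0]):
        warnings.warn(f"metric {metric!r} is constant; correlation undefined")
        return {
            "bin_centers": np.array([]),
            "p_correct": np.array([]),
            "r": np.nan,
            "p_value": np.nan,
            "degenerate": True,
        }
    order = np.argsort(values, kind="stable")
    bins = np.array_split(order, n_bins)
    centers = np.array([values[b].mean() for b in bins])
    props = np.array([correct[b].mean() for b in bins])
    r, p = pearsonr(centers, props)
    return {
        "bin_centers": centers,
        "p_correct": props,
        "r": float(r),
        "p_value": float(p),
        "degenerate": False,
    }


def _corrected_rate(hits: int, n: int) -> float:
    """Hit/false-alarm rate with the 1/(2N) correction for extreme rates."""
    if n == 0:
        return np.nan
    rate = hits / n
    if rate == 0.0:
        return 1.0 / (2 * n)
    if rate == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def behavior_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-condition percent correct, d', hit/false-alarm rates, median RT.

    A hit is a 'same' response on a match trial; d' = z(hit) - z(fa) with
    extreme rates corrected by the 1/(2N) rule.  Conditions with zero
    answered trials are omitted with a warning.
    """
    answered = trials[
        (trials["condition"] != "warmup") & (trials["response"] != "none")
    ]
    rows = []
    for cond in ("VV", "HH", "VH", "HV"):
        sub = answered[answered["condition"] == cond]
        if len(sub) == 0:
            warnings.warn(f"condition {cond} has no answered trials; omitted")
            continue
        match = sub[sub["is_match"]]
        nonmatch = sub[~sub["is_match"]]
        correct = np.where(sub["is_match"], sub["response"] == "same",
                           sub["response"] == "different")
        hit = _corrected_rate(int((match["response"] == "same").sum()), len(match))
        fa = _corrected_rate(
            int((nonmatch["response"] == "same").sum()), len(nonmatch)
        )
        rts = sub["rt_ms"].dropna()
        rows.append(
            {
                "condition": cond,
                "n_trials": len(sub),
                "percent_correct": 100.0 * float(np.mean(correct)),
                "hit_rate": hit,
                "false_alarm_rate": fa,
                "d_prime": float(norm.ppf(hit) - norm.ppf(fa)),
                "median_rt_ms": float(rts.median()) if len(rts) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
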