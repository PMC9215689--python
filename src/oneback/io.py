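"""File formats, run configuration, and the end-to-end pipeline.

All artifacts are plain CSV/JSON with stable column order and full-precision
floats so runs diff cleanly and round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from oneback import behavior, evaluation, metrics, shapes, touch

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "write_shapes",
    "read_shapes",
    "write_table",
    "read_trials",
    "read_touches",
    "read_dissimilarity",
    "run_pipeline",
]

FLOAT_FORMAT = "%.17g"

TRIAL_REQUIRED = ["trial_id", "condition", "current_shape_id", "is_match", "response"]
TOUCH_REQUIRED = ["trial_id", "pad_index", "onset_ms", "duration_ms"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run; every stage seed derives
    deterministically from ``seed``."""

    seed: int = 0
    out_dir: str = "run_output"
    n_shapes: int = 48
    generator: dict = field(default_factory=dict)
    metric: dict = field(default_factory=dict)
    observer: dict = field(default_factory=dict)
    touch: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.generator_config()
        self.metric_config()
        self.touch_params()
        self.observer_params()

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(5)
        names = ["shapes", "session", "dissim", "observer", "touch"]
        return {name: int(s) for name, s in zip(names, state)}

    def generator_config(self) -> shapes.GeneratorConfig:
        return shapes.GeneratorConfig(
            seed=self.stage_seeds()["shapes"], **self.generator
        )

    def metric_config(self) -> metrics.MetricConfig:
        return metrics.MetricConfig(**self.metric)

    def observer_params(self) -> behavior.ObserverParams:
        obs = dict(self.observer)
        obs.setdefault("intercept", -1.0)
        obs.setdefault("weights", {"hausdorff": 2.0})
        obs.setdefault("lapse", 0.05)
        return behavior.ObserverParams(seed=self.stage_seeds()["observer"], **obs)

    def touch_params(self) -> touch.TouchMCParams:
        t = {k: v for k, v in self.touch.items() if k != "curvature_gain"}
        return touch.TouchMCParams(seed=self.stage_seeds()["touch"], **t)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# CSV round-trips


def write_shapes(
    shape_map: dict[str, shapes.ShapeOutline],
    manifest: list[dict],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write one points CSV (shape_id,point_index,x_mm,y_mm) plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for sid, shape in shape_map.items():
        frames.append(
            pd.DataFrame(
                {
                    "shape_id": sid,
                    "point_index": np.arange(shape.n_points),
                    "x_mm": shape.points[:, 0],
                    "y_mm": shape.points[:, 1],
                }
            )
        )
    points_path = out / "shapes.csv"
    manifest_path = out / "manifest.csv"
    pd.concat(frames, ignore_index=True).to_csv(
        points_path, index=False, float_format=FLOAT_FORMAT
    )
    pd.DataFrame(manifest).to_csv(manifest_path, index=False, float_format=FLOAT_FORMAT)
    return points_path, manifest_path


def read_shapes(shapes_dir: str | Path) -> dict[str, shapes.ShapeOutline]:
    path = Path(shapes_dir)
    csv = path / "shapes.csv" if path.is_dir() else path
    frame = pd.read_csv(csv, float_precision="round_trip")
    missing = {"shape_id", "point_index", "x_mm", "y_mm"} - set(frame.columns)
    if missing:
        raise ValueError(f"shape CSV missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(frame[["x_mm", "y_mm"]].to_numpy())):
        raise ValueError("shape CSV contains non-finite coordinates")
    out = {}
    for sid, grp in frame.groupby("shape_id", sort=False):
        grp = grp.sort_values("point_index")
        out[str(sid)] = shapes.ShapeOutline(
            points=grp[["x_mm", "y_mm"]].to_numpy(), shape_id=str(sid)
        )
    return out


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def _read_checked(path: str | Path, required: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = set(required) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return frame


def read_trials(path: str | Path) -> pd.DataFrame:
    return _read_checked(path, TRIAL_REQUIRED)


def read_touches(path: str | Path) -> pd.DataFrame:
    return _read_checked(path, TOUCH_REQUIRED)


def read_dissimilarity(path: str | Path) -> pd.DataFrame:
    frame = _read_checked(path, ["trial_id"] + metrics.METRIC_COLUMNS)
    values = frame[metrics.METRIC_COLUMNS].to_numpy()
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite metric values")
    return frame


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: RunConfig) -> dict:
    """shapes -> session -> dissimilarities -> rankings -> touch analysis.

    Returns (and writes) a manifest with per-stage seeds, timings, and output
    hashes; a fixed seed reproduces every output byte for byte.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {"config": asdict(config), "stage_seeds": seeds, "stages": {}}
    outputs: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s (seed %s)", name, seeds.get(name))
        return time.perf_counter()

    try:
        t0 = stage("shapes")
        shape_map, shape_manifest = shapes.generate_stimulus_set(
            config.n_shapes, config.generator_config()
        )
        outputs["shapes"], outputs["shape_manifest"] = write_shapes(
            shape_map, shape_manifest, out
        )
        manifest["stages"]["shapes"] = time.perf_counter() - t0

        t0 = stage("session")
        rng = np.random.default_rng(seeds["session"])
        trials = behavior.generate_session(sorted(shape_map), rng)
        t0 = stage("dissim")
        mcfg = config.metric_config()
        dissim = metrics.compute_dissimilarity_table(
            trials, shape_map, mcfg, np.random.default_rng(seeds["dissim"])
        )
        t0 = stage("observer")
        trials = behavior.simulate_observer(trials, dissim, config.observer_params())
        outputs["trials"] = write_table(trials, out / "trials.csv")
        outputs["dissimilarity"] = write_table(dissim, out / "dissimilarity.csv")
        manifest["stages"]["session"] = time.perf_counter() - t0

        t0 = stage("evaluate")
        responses = trials.set_index("trial_id")["response"]
        conditions = trials.set_index("trial_id")["condition"]
        candidates = [c for c in metrics.METRIC_COLUMNS if c != "random_u"]
        multimetric = {}
        for cond in ("VV", "HH", "VH", "HV"):
            ranking = evaluation.evaluate_metrics(
                dissim, responses, condition=cond, conditions=conditions
            )
            outputs[f"ranking_{cond}"] = write_table(
                ranking, out / f"ranking_{cond}.csv"
            )
            chosen, fit = evaluation.select_multimetric(
                dissim, responses, candidates, condition=cond, conditions=conditions
            )
            multimetric[cond] = {
                "metrics": chosen,
                "aic": fit.aic,
                "log_likelihood": fit.log_likelihood,
                "n_obs": fit.n_obs,
            }
        summary = evaluation.behavior_summary(trials)
        outputs["behavior_summary"] = write_table(summary, out / "behavior_summary.csv")
        report_path = out / "multimetric.json"
        report_path.write_text(json.dumps(multimetric, indent=2))
        outputs["multimetric"] = report_path
        manifest["stages"]["evaluate"] = time.perf_counter() - t0

        t0 = stage("touch")
        tparams = config.touch_params()
        trng = np.random.default_rng(seeds["touch"])
        pad_models = {
            sid: touch.build_pad_model(shape, tparams, trng, mcfg)
            for sid, shape in shape_map.items()
        }
        gamma = float(config.touch.get("curvature_gain", 2.0))
        touches = behavior.simulate_touch_sequences(trials, pad_models, gamma, trng)
        outputs["touches"] = write_table(touches, out / "touches.csv")
        stats_frame, r, p = touch.touch_enrichment(touches, trials, pad_models)
        outputs["pad_stats"] = write_table(stats_frame, out / "pad_stats.csv")
        manifest["touch_enrichment"] = {"pearson_r": r, "p_value": p, "gamma": gamma}
        manifest["stages"]["touch"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc} (seeds={seeds})") from exc

    manifest["outputs"] = {k: str(v) for k, v in outputs.items()}
    manifest["hashes"] = {k: _sha256(v) for k, v in outputs.items()}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
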