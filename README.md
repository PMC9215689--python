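# oneback

A workbench for studying how well shape-dissimilarity metrics predict
same/different judgments in a one-back shape-matching task, with both visual
and haptic presentation in mind.

It provides, end to end:

- **Stimulus generation** (`oneback.shapes`) — random "blob-union" silhouettes
  built from periodic cubic splines through random control points, unioned,
  scaled to a 25 mm maximum extent, and resampled to a canonical
  counterclockwise perimeter point list at 0.1 mm spacing.
- **Shape metrics** (`oneback.metrics`) — eight dissimilarity metrics per
  shape pair: local-angle-distribution CDF error, aspect-ratio difference,
  area / convex-hull-area / compactness differences, turning-function
  distance, intersection-over-union, and Hausdorff distance.  IoU, Hausdorff
  and aspect ratio come in two variants: `actual` (at the presented
  orientations) and `optimal` (best over a rotation search whose grid always
  contains the presented offset, so `optimal` dominance is exact).
- **Session synthesis** (`oneback.behavior`) — 8-block one-back sessions
  (blocks of 72 trials, 24 match trials, 48 unique shapes, match-orientation
  deltas 0/90/180 in a 1:1:1 ratio, 144 trials per VV/HH/VH/HV condition), a
  configurable logistic observer with lapse, and curvature-biased touch
  sequences over six perimeter touchpads.
- **Metric evaluation** (`oneback.evaluation`) — binomial-GLM fits of
  responses on metric columns, AIC ranking against a stored uniform-random
  baseline (predictive = beats random by ≥ 3 AIC), forward-stepwise
  multimetric selection, actual-vs-optimal AIC contrasts, binned
  dissimilarity–accuracy curves, and percent-correct / d′ summaries.
- **Touch analysis** (`oneback.touch`) — equal-arc-length partition of each
  perimeter into six pads, a Monte Carlo baseline of random finger contact
  (touch = outside the shape, 4–6 mm from the edge), and curvature-enrichment
  statistics of observed or simulated touches.
- **I/O and pipeline** (`oneback.io`, `oneback.cli`) — CSV/JSON formats with
  lossless round-trips, a seeded end-to-end pipeline with a hash manifest,
  and a `click` CLI.

## CLI

```sh
oneback generate-shapes --n 48 --seed 1 --out shapes/
oneback simulate-session --shapes shapes/ --seed 2 --out session/
oneback compute-metrics  --shapes shapes/ --trials session/trials.csv --out dissim.csv
oneback evaluate-metrics --dissim session/dissimilarity.csv \
    --trials session/trials.csv --condition VV --out eval/
oneback touch-mc --shapes shapes/ --n 100000 --seed 3 --out baselines.csv
oneback run-all --seed 1 --out run/          # full pipeline + manifest
oneback report --run-dir run/                # plots (accuracy curve, enrichment)
```

Every command is deterministic given `--seed`; `run-all` derives each stage's
seed from the global seed and records them, with output hashes, in
`run_manifest.json`.

## Python example

```python
import numpy as np
from oneback import (
    GeneratorConfig, MetricConfig, ObserverParams,
    generate_stimulus_set, generate_session,
    compute_dissimilarity_table, simulate_observer, evaluate_metrics,
)

shapes, manifest = generate_stimulus_set(48, GeneratorConfig(seed=1))
rng = np.random.default_rng(2)
trials = generate_session(sorted(shapes), rng)
table = compute_dissimilarity_table(trials, shapes, MetricConfig(), rng)
obs = ObserverParams(intercept=-1.0, weights={"hausdorff": 2.0}, lapse=0.05, seed=3)
trials = simulate_observer(trials, table, obs)
ranking = evaluate_metrics(table, trials.set_index("trial_id")["response"])
print(ranking.head())
```

## Tests

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracles (scanline polygon-intersection areas,
nested-loop Hausdorff, explicit turning-function shift search), property
tests for the design invariants, and `tests/test_acceptance.py` with one test
per acceptance criterion.  One acceptance sub-test
(`test_coin_flip_observer_nothing_predictive`) is deliberately left failing:
the ≥ 3 AIC predictiveness rule applied to 11 metrics simultaneously has a
~30% per-replicate false-positive rate under pure-noise responses, so the
"9/10 clean replicates" bound is not statistically attainable; the test
documents this rather than hiding it.

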