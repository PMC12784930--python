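# fowlplan

Closed-loop feeding-schedule planning for cage-reared native chickens.

The package implements the full decision-support pipeline:

- **`fowlplan.synthetic`** — seeded generators for cage growth trajectories
  (Gompertz mean curve + observation noise), daily-cyclic environmental sensor
  streams with configurable per-day gas maxima, monotone per-bird intake
  profiles, and complete multi-breed/multi-batch daily record tables.
- **`fowlplan.preprocessing`** — leakage-safe model matrices: rearing-age
  computation, per-bird feed, 24-h pre-weighing environmental aggregation
  (means of temperature/RH, maxima of CO/H₂S/NH₃), train-only imputation and
  min-max scaling (z-score available), batch-wise 9:1 temporal splits,
  repeated blocked k-fold CV, and interval training pairs for the total-feed
  model.
- **`fowlplan.modeling`** — a uniform regressor contract over scikit-learn
  learners (random forest, extra trees, gradient boosting, feedforward net)
  with named hyperparameter presets, evaluation metrics (MSE/MAE/RMSE/R²), a
  variance impurity-reduction verification utility, and in-repo Monte-Carlo
  permutation Shapley attribution.
- **`fowlplan.scheduling`** — the closed loop: forecast the interval feed
  total, allocate it across days (historical profile or arithmetic
  progression), enforce daily min/max and ±10% day-to-day constraints while
  conserving the interval total, simulate the weight trajectory with the daily
  model, and proportionally correct the total until the simulated terminal
  weight hits the target. Interval FCR per plan.
- **`fowlplan.economics`** — partial-budget evaluation: feed mass saved from
  an FCR improvement and its monetary value, plus FCR contrasts between
  regimens.
- **`fowlplan.cli`** — `fowlplan` command-line tool and the end-to-end
  orchestration with seeded, manifest-stamped runs.

## CLI

```sh
# generate a synthetic dataset (3 breeds x 3 batches x 77 days by default)
fowlplan simulate-data --seed 1 --out out/data

# build model matrices
fowlplan preprocess --records out/data/daily_records.csv \
    --env out/data/env_samples.csv --out out/matrices

# train the daily weight model (extra trees preset) and the feed model
fowlplan train --matrix out/matrices/weight_matrix.csv --model et --out out/models
fowlplan train --matrix out/matrices/interval_examples.csv --model et \
    --target feed --out out/models

# attribution of an environmental-only model
fowlplan explain --model out/models/model_weight_et.joblib \
    --matrix out/matrices/weight_matrix.csv

# plan an interval: steer 785 g on day 46 to 2500 g on day 100
fowlplan schedule --model-weight out/models/model_weight_et.joblib \
    --model-feed out/models/model_feed_et.joblib \
    --start-weight 785 --target-weight 2500 --start-day 46 --target-day 100 \
    --env out/data/env_samples.csv --out out/schedule

# partial-budget feed savings
fowlplan economics --fcr0 3.42 --fcr1 3.27 --gain-kg 1.705 --n 1000 --price 14

# everything at once, with a run manifest
fowlplan run-all --seed 1 --out out/run
```

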