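# threatdyn

Decision-dynamics analysis of threat detection from mouse trajectories:
trajectory normalization and kinematic measures, multiscale sample
entropy, survey scoring, hierarchical Bayesian logistic models of
response accuracy, and k-fold ELPD/accuracy model comparison — plus a
seeded synthetic-study generator so the whole pipeline runs without any
external data.

## What's in the box

| module | role |
| --- | --- |
| `threatdyn.dataio` | CSV/JSON schemas for trajectory logs, trials, surveys; validation; the joined per-trial analysis table |
| `threatdyn.kinematics` | similarity-transform normalization to the unit 45°/135° frame; signed AUC; RT; distance-to-endpoint series |
| `threatdyn.entropy` | sample entropy with Theiler window, autocorrelation window rule, (radius × embedding-dimension) grid aggregate |
| `threatdyn.survey` | security-knowledge and indicator-use scores |
| `threatdyn.bayes_glm` | design matrices (two_factor / survey_based / real_time, full interactions), Student-t priors, partially pooled participant intercepts, posterior prediction, condition means |
| `threatdyn.sampling` | self-contained No-U-Turn sampler (dual averaging, diagonal mass adaptation) |
| `threatdyn.model_eval` | pointwise Bernoulli log densities, stratified 10-fold CV, posterior-predictive accuracy, pairwise comparison distributions, Bayesian mean-difference/slope utilities |
| `threatdyn.synthetic` | full synthetic studies: counterbalanced 2×3 design, survey records, covariates, logistic outcomes, pixel trajectories hitting AUC/entropy/RT targets |
| `threatdyn.cli` | `simulate` / `measures` / `fit` / `compare` / `reproduce` subcommands |

## CLI

All commands accept `--config <yaml>`, `--seed <int>` (overrides every
seed), `--sample {reduced,full}` (drop or keep single-response
participants), and `--out <dir>`.

```bash
# write a synthetic dataset (trajectories.csv, trials.csv, survey.csv)
threatdyn simulate --config config.yaml

# compute AUC / sample entropy / RT into out/analysis_table.csv
threatdyn measures --config config.yaml

# fit the requested models; writes fit_<name>_draws.csv + _meta.json
threatdyn fit --config config.yaml

# 10-fold ELPD + accuracy comparison; writes comparison.json / .txt
threatdyn compare --config config.yaml

# the whole chain from one seed
threatdyn reproduce --config config.yaml --seed 7
```

A minimal config:

```yaml
seed: 7
data_dir: data
out_dir: out
models: [two_factor, survey_based, real_time]
kfold_k: 10
synthetic: {n_participants: 123}
sampler: {chains: 4, draws: 1000, warmup: 1000}
```

Running without `--config` uses the defaults above (123 participants,
the full three-model comparison — the `fit`/`compare` steps then take
tens of minutes on one CPU; scale `sampler` down for quick runs).

## Notes

- File schemas are plain text (CSV with JSON mirrors); positions are
  integer pixels with the origin at top-left. The y-flip into math
  coordinates happens once, inside `normalize_trajectory`.
- Continuous model predictors are transformed (signed-log AUC, log
  entropy, log-ms RT), centered, and scaled by two standard deviations;
  transform constants are recorded per fit so held-out data project
  identically.
- Every random stage takes an explicit seed; identical seeds give
  byte-identical output files.
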