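# erpdyn

Time-resolved analysis of ERP dynamics in an auditory oddball task, built as a
tested Python package.  The pipeline covers:

- **synthetic cohorts** — a 19-channel, 500 Hz oddball-ERP generator with
  planted orthonormal scalp templates, per-window activation curves, trial
  noise, latency jitter, and clinical covariates linked to a latent
  condition-separation scalar (`erpdyn.synthetic`);
- **preprocessing** — common average reference, optional zero-phase band-pass,
  baseline correction, ±500 μV amplitude rejection, condition averaging and
  100-ms window means (`erpdyn.preprocess`);
- **ERP components** — N200/P300 mean amplitude, peak latency and inter-trial
  topographic similarity (`erpdyn.components`);
- **topographic dynamics** — window-by-window spatial correlation matrices
  between and within groups, with BH-FDR and diagonal-alignment scans
  (`erpdyn.topo`);
- **state-space trajectories** — 2-D PCA of pooled window topographies,
  inter-trajectory distance, T1-anchored angular separation, path length, and
  pseudo-population bootstrap (15 subjects/group resampling with basis
  refitting) (`erpdyn.state_space`);
- **dominant states** — PCA of the concatenated group-averaged 0–600 ms
  responses (PC1–PC4, ≥95 % variance on generator defaults), sample-wise
  projections, target−standard differences, polarity-ignored template–group
  correlations and per-state explained variance (`erpdyn.states`);
- **state sequences** — microstate-style labeling against the templates with
  an "Other" state (critical-|r| threshold), transition matrices, stability
  and targeted transition probabilities (`erpdyn.sequences`);
- **classification** — linear SVM on projection-difference features, repeated
  stratified 10-fold CV with a label-shuffle chance baseline and rank-sum
  comparison (`erpdyn.classify`);
- **statistics** — Kruskal–Wallis + Dunn–Šidák post hocs, BH-FDR, Pearson and
  partial correlation, chi-square contingency tests and the noncentral-F
  ANOVA sample-size search (`erpdyn.stats`).

## CLI

All stages are exposed under one entry point:

```bash
erpdyn simulate --config gen.yaml --out cohort/ --seed 1
erpdyn preprocess --in cohort/ --out clean/
erpdyn erp --in cohort/ --out components.csv
erpdyn trajectories --in cohort/ --boot 1000 --n-per-group 15 --seed 1 --out traj/
erpdyn states --in cohort/ --k 4 --out states/
erpdyn transitions --in cohort/ --alpha 0.05 --out trans/
erpdyn classify --in cohort/ --folds 10 --repeats 500 --seed 1 --out clf.json
erpdyn stats --in metrics.csv --design group --out stats.csv
erpdyn run --config run.yaml --out results/ --seed 1   # full pipeline
```

`erpdyn run` executes simulate → preprocess → components → topographies →
trajectories (+bootstrap) → dominant states → transitions → classification →
statistics, writing CSV/JSON outputs plus a deterministic `summary.json`
(wall-clock timings go to `timings.json` so reruns are checksum-identical).
Epoched data live in a simple container: a little-endian float32 payload
(channels × samples × trials) next to a JSON sidecar.

## Reproducibility

Every stochastic operation takes an explicit seed; `simulate_cohort` is
byte-identical for a fixed seed, and the pipeline derives all stage seeds
from the single master seed in the run configuration.
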