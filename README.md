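# conncog

Multimodal brain-connectome prediction of cognitive performance, built as a
fully testable pipeline driven by a synthetic-cohort generator:

- **`conncog.synthetic`** — synthetic cohorts: near-balanced 400-node/7-network
  parcellations, community-structured node time series, sparse streamline-count
  SC matrices, regional GMV with age decline, demographics (age 55–85, sex,
  ISCED-like education, eTIV) and a 14-test cognitive battery whose scores
  depend on demographics and a latent brain factor planted in a known sparse
  node set (recorded in a truth record together with the achieved R²).
- **`conncog.features`** — FC construction (Pearson correlation, Fourier
  phase-randomized surrogate edge-significance filtering with add-one
  permutation p-values, Fisher r-to-z, positive/negative parts), SC log
  transform, nodal within-/inter-network connectivity and ratio scores, and
  assembly of feature sets A (2000), B (1200), C (2800) and the full
  concatenation (2800 columns on 400 nodes), optionally with demographic
  extra features.
- **`conncog.cognition`** — battery targets: sex × age-band median imputation,
  z-scoring with inversion flags, PCA global composite, eigenvalue>1 profile
  solution with Varimax rotation and regression-method scores, KMO index,
  theoretical (mean z-score) composite.
- **`conncog.ml`** — repeated nested 10×10-fold CV with inner 5-fold
  hyperparameter search by MAE, train-side scaling and target confound
  regression (eTIV only, or eTIV + age/sex/education), concatenation and
  fold-preserving two-layer stacking with a random-forest meta-estimator,
  dummy baselines, per-fold MAE/R²/r bookkeeping, and the extreme-group
  classifiers.
- **`conncog.evaluation`** — multimodal bonus scores (B_all / B_best), top-20
  feature-importance intersection across algorithms and feature sets, modality
  ranking from the stacking meta-estimator, extreme-group construction,
  propensity-score matching with balance diagnostics, partial correlations.
- **`conncog.io` / `conncog.pipeline` / `conncog.cli`** — plain-text formats
  (delimited matrices, CSV, JSON manifest), stage orchestration with caching,
  and the command-line interface.

## CLI

```sh
conncog run --out runs/demo --seed 7                 # full pipeline, defaults
conncog simulate --out runs/demo --n-subjects 120 --n-nodes 60
conncog features --out runs/demo --fset A --n-perm 1000 --alpha 0.05
conncog targets  --out runs/demo
conncog predict  --out runs/demo --approach stack --algorithms ridge,en \
                 --deconf deconf --extra-features --outer-k 10 --repeats 10
conncog report   --run runs/demo/manifest.json
```

Every flag can also be set in a YAML config (`--config`); flags win. All
randomness flows from the single `--seed`. Rerunning an unchanged config in
the same directory reuses cached stage products; rerunning in a fresh
directory reproduces outputs bit-identically.

The default pipeline configuration is a desk-scale smoke setting (60 nodes,
120 subjects, reduced hyperparameter grids). Pass `--full-grids` and the full
`--outer-k 10 --repeats 10` for the complete printed protocol.

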