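# eegfatigue

A tested pipeline for limited-channel EEG fatigue detection with the
four-electrode headband montage (TP9, AF7, AF8, TP10) at 256 Hz:

1. **synthetic** — generates cohorts of EEG-like recordings (band-limited
   oscillations over a pink/white noise floor) plus subjective fatigue
   scores, with configurable fatigue-dependent spectral and complexity
   shifts injected into chosen channels, so every downstream stage is
   testable without any data download.
2. **segmentation** — partitions each session into the ordered events
   s1, m1, s2, m2, s3, m3 (fixed durations, variable s3) and cuts
   non-overlapping 2560-sample (10-s) windows.
3. **features** — a 16-feature battery per window: statistical moments,
   seven entropies (sample, fuzzy, Shannon, Renyi, permutation,
   distribution, SVD) and Welch band powers (delta/theta/alpha/beta) plus
   spectral entropy; windows are averaged to one representative vector
   per (subject, session, channel, event).
4. **labelling** — binary fatigue labels from subjective-score thresholds
   (physical: mean of high-intensity-session physical scores; mental:
   mean of all mental scores; inclusive `score >= threshold` rule).
5. **modelling** — leave-one-subject-out (LOSO) cross-validation,
   SMOTE-style minority oversampling applied to training folds only,
   exhaustive hyperparameter grids for logistic regression, gradient
   boosting and SVM, and base-classifier selection with recall as the
   tie-breaker.
6. **evaluation** — the cost-weighted Score
   `(w * recall + (1 - w) * specificity) * 100` (default `w = 0.8`),
   LOSO evaluation and ranking of all 15 channel combinations,
   feature-group ablation (7 configurations) and task-stratified
   confusion analysis.
7. **workflow** — YAML-configured, fully seeded end-to-end runs with
   diffable JSON/CSV artifacts.

## CLI

```bash
eegfatigue run --seed 1 --out run/            # full pipeline, defaults
eegfatigue run --config cfg.yaml --out run/   # YAML RunConfig overrides
eegfatigue simulate|extract|label|train|rank|ablate --out run/
eegfatigue report --out run/
```

Artifacts written per run: cohort manifest and scores, feature table,
modelling table, label policy, grid-search candidates, selected model,
channel-combination metrics, pooled and per-context confusion counts,
ablation table and a consolidated `report.json`. Identical configs give
byte-identical reports.

## Notes

- Sample/fuzzy entropy share one O(N^2) template-matching kernel (numba
  when available, chunked numpy otherwise); both are verified against
  brute-force oracles.
- Oversampling, standardisation and model fitting happen strictly inside
  each training fold; synthetic rows can never reach a test fold.
- All randomness flows from one master seed through a documented
  `SeedSequence` derivation (`eegfatigue._seeds`).
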