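# smrhythm

Quantification of cortical sensorimotor resting-state activity from
single-channel time series: aperiodic (1/f) and periodic (alpha/beta)
spectral features, transient mu-beta burst features, and two Bayesian
regression analyses — exercised end-to-end on synthetic signals and cohorts
with known ground truth.

## What it does

- **`smrhythm.synthgen`** — synthetic recordings whose PSD is an exact
  power-law background plus optional log-Gaussian oscillatory peaks;
  Poisson trains of Hann-windowed sinusoidal bursts with ground-truth event
  lists; cohorts (group/age/sex/cortical thickness, clinical subscales)
  with configurable Gaussian-linear and Poisson log-linear effect
  structure.
- **`smrhythm.spectral`** — Welch PSD (3.072 s Hann segments, 50 % overlap,
  0.5–40 Hz) and an iterative aperiodic + Gaussian-peak decomposition
  (fixed-mode log-log aperiodic fit, robust refit, ≤ 8 peaks, peak
  threshold 2 SD, minimum height 0.05, bandwidth 0.75–12 Hz), band-peak
  selection in the alpha (8–12 Hz) and beta (13–30 Hz) bands, plus the
  uncorrected raw-PSD band maxima.
- **`smrhythm.bursting`** — zero-phase FIR band-pass (8–30 Hz) + Hilbert
  envelope; burst detection at 2× the envelope median with half-max or
  threshold-crossing event edges; per-subject rate / duration / interval /
  amplitude summaries.
- **`smrhythm.inference`** — sequential BIC-approximated Bayes-factor model
  comparison (Gaussian, or Poisson with exposure offset for burst counts)
  for `feature ~ group + age + age² + sex + thickness (+ two-way
  interactions)`; percent-effect back-transforms; clinical multiple
  regressions (symptom subscale ~ ten signal features + covariates) with
  leave-one-predictor-out Bayes factors; Welch t and Yates chi-square
  demographics tests.
- **`smrhythm.workflow`** — YAML-configured pipeline (`simulate` →
  `features` → `stats`) with tidy CSV/TSV/JSON outputs.

## CLI

```sh
# synthetic cohort + recordings, feature extraction, both analyses:
smrhythm all --n-subjects 20 --duration-s 180 --out runs/demo

# or stage by stage:
smrhythm simulate --n-subjects 20 --out runs/demo
smrhythm features --recordings-dir runs/demo/recordings --out runs/demo
smrhythm stats --features-csv runs/demo/cohort.csv --out runs/demo
```

Recordings are read as two-column delimited text (`time_s<TAB>value`) or
raw little-endian float64 arrays with a JSON sidecar. Outputs:
`features.csv`, `events.tsv` (BED-like), `results.csv` (tidy
outcome/predictor/estimate/CI/BF10), `report.json` (settings, demographics,
flagged predictors with BF > 3), `run.log`.

Default settings (Welch segment 3.072 s, 50 % overlap,
0.5–40 Hz; 8 peaks / threshold 2 / min height 0.05 / bandwidth 0.75–12 Hz;
burst band 8–30 Hz, threshold 2× median, half-max edges) can be
overridden via `--config config.yaml`.

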