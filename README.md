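# sleepscope

A polysomnography (PSG) analysis pipeline for insomnia-vs-control group
contrasts on central-electrode EEG, plus a synthetic cohort generator so the
whole pipeline can be exercised end-to-end without clinical data.

Feature families computed per recording:

- **Macro-architecture & transitions** — TST, sleep efficiency, WASO, latency
  to persistent sleep (first run of 20 consecutive non-wake epochs), objective
  insomnia/control screens, and the 5×5 stage-transition count matrix
  (25 features, stage order W/N1/N2/N3/R).
- **Spectral** — multitaper (2-s DPSS windows, 1-s hop) band powers in
  δ 0.5–4 / θ 4–8 / α 8–12 / β 12–30 Hz, RMS artifact masking (3-s segments,
  ≤1 µV or ≥250 µV), C3+C4-summed relative power per 30-s epoch, log stage
  means (20 features).
- **Spindles & slow oscillations** — 13.5 Hz Morlet detection in N2 with
  4.5×/2× thresholds, 0.5-s merging and 3-s rejection; SOs as 0.8–2 s
  positive-to-negative zero-crossing intervals of the 4.5 Hz low-passed
  signal; density, dispersion (Fano factor) and SO-phase-at-peak for
  fast/slow spindles per channel (8 features).
- **Wake EEG Similarity Index (WESI)** — per 3-s window, logit-transformed
  relative band powers, z-scored on the training split, expanded to 14
  predictors (4 linear + 6 products + 4 squares) and fed to a 15-parameter
  L1-regularized logistic model with a Huberized loss (λ=0.1, δ=3, 80/20
  split). Per-stage score means (5 features) are analysed on the logit scale
  and reported on the score scale via a finite-difference back-transform
  validated against a 10,000-resample bootstrap.
- **Group statistics** — null / main-effect / interaction mixed models
  (age centred at 50, sex, group, random site intercept), likelihood-ratio
  tests, Benjamini–Hochberg FDR with fixed family sizes (spectral 180,
  spindle 14, WESI 10, transition 25), and prevalence-gated hurdle /
  GLMM models for transition counts (1.5 % / 98.5 % gates) with the
  two-condition significance rule.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (structural counts,
detector/spectral oracles, WESI learning checks, statistical calibration,
hurdle routing).

## CLI

```bash
sleepscope simulate --n-insomnia 5 --n-control 5 --minutes 30 --seed 1 --out cohort/
sleepscope preprocess cohort/S0000.edf cohort/S0000_hypnogram.csv --out mask.csv
sleepscope features cohort/S0000.edf cohort/S0000_hypnogram.csv --out feats.csv
sleepscope run-all --n-insomnia 8 --n-control 8 --minutes 30 --seed 1 --out report/
```

`run-all` writes a report bundle (features.csv, sleep_summary.csv,
results_<family>.csv, transition_grid.csv, manifest.json) and accepts a YAML
config via `--config`.

## Package layout

```
src/sleepscope/
  types.py            shared domain types (Hypnogram, EEGRecording, events)
  edfio.py            minimal EDF reader/writer
  synthetic_cohort.py synthetic PSG cohorts with planted ground truth
  preprocess.py       re-reference -> resample(200 Hz) -> 0.5 Hz HP -> 50 Hz LP; RMS mask
  hypnogram_metrics.py sleep summaries, PSG criteria, transition counts
  spectral.py         multitaper band powers, per-stage relative features
  spindle_so.py       spindle/SO detection and coupling features
  wesi.py             wake-similarity model, scoring, back-transform
  group_stats.py      mixed models, LRT, FDR, hurdle transitions
  pipeline.py / cli.py end-to-end orchestration and CLI
```
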