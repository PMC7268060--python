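# erdpipe

A tested, reusable pipeline for longitudinal EEG biomarker analysis of motor
recovery: from raw multichannel EEG/EMG trials through automated artifact
rejection and event-related desynchronization (ERD) extraction to a
two-stage statistical model linking ERD trajectories to clinical
improvement, including a progressive laterality coefficient (pLC).

Because no public dataset exists for this protocol, the package ships a
first-class synthetic-cohort generator with known ground truth; every
downstream stage is validated against it.

## What it does

- **`erdpipe.synthetic`** — simulates training sessions (16 EEG + 2 EOG +
  8 EMG channels at 500 Hz; trials of 4–7 s inter-trial interval, 2 s
  preparation, 5 s movement). Motor-region channels carry an alpha
  oscillation over pink + white noise whose movement-phase amplitude encodes
  a target ERD exactly (`sqrt(1 + ERD/100)` scaling). Per-subject linear
  ERD-vs-session trajectories with bivariate random effects, a stage-2
  interaction outcome model for clinical change, and injectable
  EOG/high-frequency/offset/limb-EMG artifacts with a full ground-truth log.
- **`erdpipe.io`** — EDF and BrainVision readers (plus writers for
  round-trips), channel-role mapping, sidecar event tables and phase-labeled
  epoching (rest = last 4 s of the ITI).
- **`erdpipe.artifacts`** — the automated cascade: ICA-based EOG component
  removal, 110–140 Hz z-score detector (threshold 4 SD), broadband offset
  detector (20 SD), EMG waveform-length contraction timing rules
  (paretic-rest / healthy-move), and session/subject exclusion rules
  (< max(16, 10%) trials ⇒ session out; ≥ half of sessions out ⇒ subject out).
- **`erdpipe.spectral`** — Welch band power (1 s Hann, 50% overlap),
  per-trial ERD = (M−R)/R×100 averaged over three channels per hemisphere,
  hemisphere mapping by lesion side, and individual SMR-band calibration via
  r² discriminability of rest vs movement log band power.
- **`erdpipe.modeling`** — stage 1: linear mixed-effects model
  `erd ~ session` with correlated random intercept+slope per subject (REML
  by default, statsmodels), per-subject coefficients as fixed effect +
  conditional mode; stage 2: OLS of clinical change on intercept, slope and
  their interaction; median-split subgroup regressions; pLC = S_healthy −
  S_lesion and its regression; likelihood-ratio model comparison.
- **`erdpipe.pipeline` / CLI** — end-to-end orchestration producing a
  reproducible bundle (rejection report, tidy ERD table, model JSON,
  figures, Markdown report, MANIFEST).

## CLI

```sh
erdpipe run --config src/erdpipe/configs/paper_like.yaml    # 22 subjects x 17 sessions (ERD-level)
erdpipe run --config src/erdpipe/configs/smoke_signal.yaml  # small raw-signal end-to-end run
erdpipe simulate --seed 1 --out cohort/ --materialize --n-trials 8
erdpipe reject  --data-dir cohort/ --out rejection.tsv
erdpipe erd     --data-dir cohort/ --out erd.tsv
erdpipe model   --erd cohort/erd_targets.tsv --outcomes cohort/outcomes.tsv --out model.json
erdpipe report  --bundle results/paper_like
```

The `paper_like` config runs at the ERD level (session-mean ERD targets feed
the models directly): materializing raw signals at the full protocol scale
(22 × 17 sessions × 165 trials × 26 channels × 500 Hz) is far beyond a
desktop budget and adds nothing to the statistics. The `smoke_signal` config
exercises the complete raw-signal path at reduced scale.

## Notes

- Outputs carry no timestamps; identical seeds give byte-identical bundles.
- Stage-2 p-values are reported without multiple-testing correction
  (matching the analysis design this mirrors); treat them accordingly.
- Supported recording formats are EDF and BrainVision; events come from
  marker files or a sidecar TSV (`onset_s`, `iti_s`).
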