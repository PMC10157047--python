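# erpsel

ERP feature extraction and exhaustive best-subset regression with
leave-one-out cross-validation, plus a synthetic evoked-potential generator
so the whole pipeline is testable offline.

The pipeline has three stages:

1. **`erpsel.synth`** — generates integer trait scores (truncated normal),
   trial schedules (5 sets × 60 trials at an AW:RW:ST ratio of 2:2:1, i.e.
   120/120/60 trials), and continuous 8-channel recordings at 250 Hz in which
   the two walking conditions carry a negative ~170 ms and a positive
   ~200 ms component on the temporal channels (T5/T6). Component latency and
   amplitude can depend linearly on the trait score; 1/f-shaped noise and
   blink-like EOG artifacts are injectable. Datasets round-trip through a
   columnar TSV format (optionally gzipped) with JSON sidecars.
2. **`erpsel.erp`** — zero-phase 1–20 Hz band-pass, epoching into
   [−200, 600) ms windows, baseline correction over [−200, 0) ms,
   peak-to-peak artifact rejection against the EOG channels (default
   100 µV), per-condition averaging with standard errors, grand averages,
   windowed peak detection for both components, and assembly of the
   per-electrode feature table (8 indicators: latency/amplitude × two
   components × AW/RW). Participants with unidentified peaks at an
   electrode are excluded there, with reasons logged.
3. **`erpsel.essearch`** — fits all 2^N − 1 nonempty predictor subsets
   (255 for N = 8) by OLS, scores each by the mean absolute error of its
   leave-one-out predictions (CVE), ranks models by ascending CVE
   (ties: fewer predictors, then bitmask), and reports standardized partial
   regression coefficients as a weight diagram with per-variable selection
   counts. LOOCV uses the exact hat-matrix identity; the test suite verifies
   it against a naive refit-per-fold oracle.

`erpsel.orchestrate` wires the stages together behind a YAML config and
writes a reproducible report bundle (TSV/JSON plus a checksummed manifest)
and figures.

## CLI

```sh
erpsel synth   --out data/ --seed 1 --n-participants 30   # write a dataset
erpsel extract --data data/ --out features/               # feature tables
erpsel regress --features features/features_T5.tsv \
               --electrode T5 --topk 50 --out results/
erpsel run     --config config.yaml                       # full pipeline
```

`erpsel run` with no config uses the default synthetic configuration
(30 participants, 300 trials each) and writes feature tables, exclusion log,
grand-average traces, CVE tables, weight diagrams, selection frequencies,
best-model reports and a manifest under `results/run/`.

A minimal YAML config:

```yaml
mode: synthetic
out_dir: results/demo
seed: 7
top_k: 50
generative:
  n_participants: 30
  noise_sd: 10.0
  latency_slopes: {P200/AW/T6: 0.5}
  amplitude_slopes: {P200/AW/T5: -0.1, P200/AW/T6: -0.1}
erp:
  band_hz: [1.0, 20.0]
  reject_threshold_uv: 100.0
```

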