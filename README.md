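# ephysqc

Automatic quality assessment of intracellular (sharp-electrode style)
electrophysiological recordings.

The package implements a fully automated pipeline that mimics an expert's
judgement of recording quality:

1. **Spike detection** (`ephysqc.spike_detection`) — moving-average filtering
   (3 ms window), percentile-derived derivative thresholds (3×P80 up,
   3×P20 down), candidate events from consecutive-run criteria, per-event
   characterisation against a local baseline, and two eligibility rules that
   reject step artefacts and small secondary events.
2. **Feature extraction** (`ephysqc.feature_extraction`) — 16 per-recording
   features: spike height/width statistics, trimmed baseline statistics,
   short-timescale RMS noise, linear drifts, minimum ISI and spike-slope
   statistics.
3. **Classification** (`ephysqc.quality_model`) — linear one-vs-one SVM
   (C = 512, 10^4 iteration cap), repeated 10-fold cross-validation,
   exhaustive wrapper feature selection over all 2^16−1 subsets, top10
   groups, majority-voting ensembles, a bias-free two-stage leave-one-out
   evaluation, and cross-dataset evaluation.
4. **Synthetic data** (`ephysqc.synthetic_traces`) — a generator for
   labelled good/intermediate/bad traces with controllable spike shape,
   firing statistics, noise, drifts and step/transient artefacts, with exact
   ground truth, so the entire pipeline is testable offline.
5. **Reporting** (`ephysqc.reporting`) — per-class feature histograms,
   KS tests with Bonferroni correction, PCA projections, chance levels,
   feature-use statistics and agreement tables.

Quality labels are `bad` / `intermediate` / `good`, encoded numerically as
−1 / 0 / +1; the merged 2-class problem pools `bad` and `intermediate` into
`unacceptable`.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks the wrapper
combinatorics, chance-level arithmetic, detector/feature/selection validity
on synthetic ground truth, the bias protection of the two-stage
leave-one-out procedure, and end-to-end determinism. The full run takes
roughly 10 minutes on one CPU (dominated by the exhaustive wrapper checks).

## Command line

```sh
# generate a labelled synthetic corpus (default 100/54/29 traces)
ephysqc simulate --out corpus/ --counts 20,10,10 --seed 1

# 16-feature table
ephysqc extract --traces corpus/ --out features.csv

# exhaustive wrapper feature selection (reduced scale shown)
ephysqc wrapper --features features.csv --labels corpus/labels.csv \
    --sizes 1-6 --repeats 5 --seed 1 --out wrapper.json

# train / predict
ephysqc train --features features.csv --labels corpus/labels.csv \
    --subset 1,4,13 --out model.json
ephysqc predict --model model.json --features features.csv --out pred.csv

# bias-free two-stage leave-one-out estimate
ephysqc loo2 --features features.csv --labels corpus/labels.csv \
    --sizes 1-3 --out loo2.json

# cross-dataset evaluation and descriptive reports
ephysqc crosseval --train-features f1.csv --train-labels l1.csv \
    --test-features f2.csv --test-labels l2.csv \
    --wrapper-result wrapper.json --out cross.csv
ephysqc report --features features.csv --labels corpus/labels.csv --out report/
```

Trace files are plain CSV with a `#`-prefixed metadata header (id,
sampling_rate, gain, stimulus metadata) and either one `voltage` column or
two `time_s,voltage` columns; see `ephysqc.trace_io`.

## Conventions

- percentiles use linear interpolation between order statistics;
- standard deviations are population (divide by N) throughout;
- millisecond windows convert to samples by rounding half away from zero;
- detection runs on the filtered trace's derivative; spike maximum,
  baseline, height and width are measured on the raw trace;
- degenerate traces (fewer than 2 accepted spikes) receive fill values that
  keep feature vectors finite (zeros; minimum ISI = trace duration).
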