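# gazemark

An eye-tracking biomarker pipeline on synthetic cohorts: from raw gaze
samples through region-of-interest (ROI) derivation and quality-control
gating to the Oculomotor Index of Gaze to Human Faces (OMI), pupillary
light-reflex (PLR) metrics, and a full psychometric evaluation battery
(acquisition rates, construct validity, six-week stability, group
discrimination, clinical correlations).

Because the study-scale raw recordings live in a controlled-access
repository, a first-class **synthetic cohort simulator** stands in for them.
It is calibrated so that realized per-participant task means and SDs,
the OMI group difference, test–retest ICCs, and biomarker–clinical Spearman
correlations hit configurable targets (defaults follow the reference
cohort summary statistics).

## Layout

| module | role |
| --- | --- |
| `gazemark.config` | pydantic configuration (simulation targets, trial plan, thresholds) |
| `gazemark.calibrate` | moment calibration: logit-normal targets, Markov dwell variance, trait/state split |
| `gazemark.simulate` | cohort generator (gaze streams, pupil traces, clinical tables, ground truth) |
| `gazemark.rois` | ROI schema (JSON), geometry tests, synthetic stimulus layouts |
| `gazemark.derive` | per-trial ROI dwell percentages, %Valid Data, calibration error |
| `gazemark.pupil` | PLR preprocessing, latency (acceleration minimum), relative constriction |
| `gazemark.qc` | trial/session/timepoint gating, task summaries, OMI, acquisition report |
| `gazemark.psychometrics` | one-sample construct tests, ICC (consistency + absolute), HC3-robust group contrasts, plain/partial Spearman |
| `gazemark.pipeline` / `gazemark.cli` | orchestration and the `gazemark` command |

## CLI

```bash
gazemark all --seed 1 --outdir out          # simulate -> derive -> qc -> reports
gazemark simulate --outdir out --n-asd 20 --n-td 20
gazemark derive out/gaze.csv out/battery_spec.json --pupil out/pupil.csv --out trials.csv
gazemark qc trials.csv out/clinical.csv --outdir qc_out
gazemark psychometrics qc_out/biomarker_table.csv --outdir reports
gazemark report qc_out/summaries.csv qc_out/omi.csv out/clinical.csv --outdir reports
```

All formats are delimited text (CSV) plus JSON for configurations and ROI
battery specs. Identical configuration + seed produces byte-identical
outputs. Exit codes: 2 configuration error, 3 data error, 4 analysis error.

The default configuration simulates the full cohort (280 + 119 participants,
two timepoints, two days each) — at the default 50 Hz that is several million
samples; pass a smaller `n_asd`/`n_td` or a reduced `sample_rate_hz` for
desk-scale experiments (dwell-time percentages are sampling-rate invariant).

## Notable conventions and caveats

* Screen coordinates: origin top-left, x right, y down, pixels, half-open
  bounds `[0, W) x [0, H)`; angles in visual degrees (configurable
  px/degree); times in ms; proportions reported as percentages 0–100.
* ROI overlap is resolved by fixed precedence (face over body over activity).
* Gating thresholds (50% valid data, 2.5 deg calibration error, 25% valid
  trials, 70% validity benchmark) are inclusive at the boundary and
  configurable.
* PLR latency is the time from flash to the minimum of the smoothed
  diameter's second derivative (Savitzky–Golay differentiation). On
  noiseless traces it is exact to one sample period; with measurement noise
  it carries a small negative bias (a few ms at the default noise level),
  shared across groups. Relative constriction uses the diameter (not area)
  ratio.
* The PLR trial-validity rule (coverage ≥ 50% in baseline and response
  windows, latency inside (0, 1000] ms, constriction inside (0, 1)) is this
  package's definition.
* Two ICC variants are computed (consistency and absolute agreement,
  two-way, k = 2); the absolute-agreement variant is the default column.
* No multiple-comparison adjustment is applied anywhere.
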