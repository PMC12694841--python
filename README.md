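# veogblink

Spontaneous-blink biomarker pipeline: extract blink events from a bipolar
vertical EOG (VEOG), compute four per-segment blink indices, and run the
associated statistical layer — all validated end-to-end against a
ground-truthed synthetic VEOG generator.

The blink indices are:

| Index | Meaning |
| ----- | ------- |
| BR    | blink rate (blinks/min) |
| BA    | blink amplitude: mean peak voltage (µV) over detected blinks |
| BRV   | coefficient of variation (sample SD / mean) of inter-blink intervals |
| BAV   | coefficient of variation of per-blink peak amplitudes |

Processing defaults: 0.5–20 Hz zero-phase band-pass (4th-order Butterworth,
forward–backward), peak detection at a 100 µV threshold with a 250 ms
refractory interval (larger peak wins; ties go to the earlier peak).

## Layout

- `signal_io` — EDF/EDF+ and delimited-text ingestion (µV convention),
  bipolar upper-minus-lower derivation, half-open segment slicing.
- `preprocessing` — band-pass filtering per analysis segment.
- `blink_detection` — thresholded peak-picking with refractory pruning;
  inter-blink intervals.
- `blink_metrics` — BR/BA/BRV/BAV per segment and within-subject film
  aggregation (NaN sentinels for under-populated indices).
- `synthetic_veog` — gamma-renewal blink timing, lognormal amplitudes,
  waveform rendering with exact ground truth, and Gaussian-copula cohorts
  hitting configured anxiety–blink correlation targets (with an optional
  full-mediation structure).
- `stats_models` — pairwise Pearson matrices, random-intercept mixed models
  (own REML fitter with Satterthwaite F tests and marginal R²), single-mediator
  analysis (Sobel + seeded percentile bootstrap), Welch's t.
- `cli_pipeline` — `blink` command-line tool and the all-in-one runner.

## CLI

```bash
# simulate a ground-truthed cohort (writes cohort CSVs; optionally renders
# full 500 Hz per-subject trace CSVs with ground-truth event tables)
blink simulate --config config.yaml --seed 1 --out-dir sim/ --render-subjects 1

# detect blinks on a recording (CSV with header row, or EDF)
blink detect --input sim/S001_trace.csv --fs 500 --upper Ve1 --lower Io1 \
    --segments sim/S001_segments.csv --out events.csv

# per-segment indices from an events table
blink metrics --events events.csv --segments sim/S001_segments.csv --out metrics.csv

# correlation matrix; for the film session also mixed models + mediation
blink analyze --metrics metrics.csv --subjects sim/cohort.csv --session film --out report/

# simulate -> metrics -> analyze in one go, with an output manifest
blink run --config config.yaml --seed 1 --out-dir out/
```

Config files are plain YAML whose keys mirror `CohortParams`
(`n_subjects`, `effects`, `mediation`, `br_mean`, …).  Every stochastic
stage takes an explicit seed; identical config + seed reproduce outputs
byte-for-byte (verified via manifest hashes).

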