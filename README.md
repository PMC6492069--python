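# circamood

Circadian digital-phenotype analysis: from raw per-patient wearable/phone
streams (minute heart rate, minute steps, light samples, nightly sleep,
daily mood scores, clinician episode intervals) to 130 circadian features
per patient-day, absolute-mood-score (AMS) labels, and rolling-origin
random-forest evaluation — plus a synthetic cohort generator with known
circadian structure so the whole pipeline is testable without clinical data.

## Pipeline

1. **synthetic** — simulate a cohort: cosinor heart rate, solar-anchored
   activity/light, jittered sleep, a 4-state episode Markov chain
   (NE/DE/ME/HME) driving a latent instability, and a single `coupling`
   knob linking circadian disruption to mood (coupling 0 ⇒ mood carries no
   sensor signal).
2. **ingest** — documented CSV schemas, validation with rejection counts,
   and the complete-row filter (a row survives only if all 130 features and
   the mood score are present).
3. **solar** — NOAA-style sunrise/sunset (±5 min), overridable by a
   `suntimes.csv` table; *daytime* = `[sunrise, sunset)`, *bedtime* = the
   8-hour window ending at sunrise.
4. **cosinor** — OLS fit of a 24-h cosine to each trailing 48-h HR window:
   mesor, amplitude, acrophase (clock time of peak), R².
5. **features** — 13 basic features per day (steps/light by timeslot, sleep
   length/efficiency/onset- and offset-regularity, 4 cosinor parameters,
   resting HR), expanded with mean/SD/gradient over the trailing 3/6/12
   days to 130 columns (see `docs/feature_dictionary.md`).
6. **labeling** — AMS = |mood score|; 2-class *biased*/*neutral* mood state
   from a percentile cutoff (10/30/50%) of the forward 3-day mean AMS;
   4-class episode labels from clinician intervals.
7. **modeling** — random forests under rolling-origin evaluation
   (train `[t−p, t]`, test `[t+1, t+q]`; mood-state labels are thresholded
   on the training window by default, and the last 3 training days are
   embargoed because their forward labels overlap the test window), a
   (p, q) sweep, signed feature importances, sensor-family ablations, and
   general-vs-personalized comparison.

## CLI

```bash
circamood simulate --config sim.yaml --out run/data
circamood extract  --data run/data --out run/features.csv
circamood label    --matrix run/features.csv --cutoff 50 --out run/labeled.csv
circamood evaluate --matrix run/features.csv --p 18 --q 3 --out run/report.json
circamood sweep    --matrix run/features.csv --p-values 6,12,18 --q-values 3,6 --out run/sweep.csv
circamood ablate   --matrix run/features.csv --out run/ablation.csv
circamood compare  --matrix run/features.csv --out run/personalized_vs_general.csv
circamood report   --matrix run/features.csv --out run/hams_lams.csv --plot run/hams_lams.png
```

`sim.yaml` takes any `SimConfig` field (`n_patients`, `n_days`, `coupling`,
`hr_*`, `missing_rates`, `seed`, …); omit `--config` for defaults.

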