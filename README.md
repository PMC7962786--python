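# gazecraft

Task-dependent gaze analysis for free-viewing experiments: from raw
1000 Hz gaze samples to saccade/fixation events, inter-observer congruence
(leave-one-out Normalized Scanpath Saliency), spatial dispersion,
duration-weighted heatmaps, ordinal temporal profiles and the full
mixed-model statistical battery — plus a synthetic gaze-study generator
that provides exact ground truth for every downstream stage.

## What it does

- **Event detection** — saccades from smoothed sample velocities with a
  combined 30 °/s velocity OR 8000 °/s² acceleration threshold; fixations
  as everything that is neither saccade nor blink; blink, off-image and
  blink-adjacent fixation removal; ratio-based saccade artifact exclusion
  (duration/amplitude and path-length/amplitude rules).
- **Scanpath metrics** — Gaussian fixation maps (σ = 1.5° of visual angle),
  per-observer leave-one-out NSS over same-image/same-task peers, spatial
  dispersion in (0, 1], mass-normalized group heatmaps and difference maps.
- **Statistics** — linear mixed models with crossed random intercepts for
  subject and image (maximum-likelihood, exact profile likelihood via the
  Woodbury identity), likelihood-ratio tests per fixed effect,
  ANCOVA-based repeated-measures correlation, ordinal 2–13 event profiles
  and behavioral summary tables with binomial above-chance flags.
- **Simulation** — complete synthetic studies (13 experts + 14 non-experts ×
  36 images × 3 tasks by default) with central-bias first fixations,
  lognormal fixation durations drifting with ordinal number, saccade
  amplitudes carrying group/task effects, a congruence parameter that
  controls how strongly observers share image regions, and injected blinks
  and hook-shaped artifact saccades.

## CLI

```sh
# full pipeline on a synthetic study
gazecraft run --synthetic --seed 7 --out out/

# from a YAML config (see out/config.yaml of any run for the schema)
gazecraft run --config cfg.yaml --out out/

# generate a study to CSV + ground truth
gazecraft simulate --seed 7 --subjects 8 --images 6 --out sim/

# events + NSS/dispersion from recorded data
gazecraft metrics --samples sim/samples.csv --trials sim/trials.csv --out out/

# behavioral summaries / rmcorr / ordinal profiles from saved tables
gazecraft stats --trials sim/trials.csv --events out/events.csv --out stats/
```

Input CSV dialects: samples `trial_id,t_ms,x_px,y_px,valid` and trials
`trial_id,subject_id,group,image_id,task,presentation_ms,answer,correct,
confidence_raw,familiarity_raw`. An EyeLink-ASC-like reader is available
via `read_samples(path, dialect="asc")`.

Each run writes `events.csv`, `metrics.csv`, `behavior_summary.csv`,
`stats.json`, `report.txt` and a `manifest.json` whose config hash and seed
reproduce the run bit-exactly in synthetic mode.

## Notes on defaults

- The printed duration/amplitude exclusion threshold (1.5) is
  unit-ambiguous; read as ms/deg it excludes essentially all physiological
  saccades. `FilterParams` defaults to the literal ms reading, the
  pipeline config defaults to seconds, both are configurable, and the
  pipeline warns whenever the filter removes more than half of all
  saccades.
- Maps are computed over the image pixel rectangle (off-image fixations are
  removed beforehand); `grid_step` trades resolution for speed without
  changing z-scores or dispersion beyond grid quantization.
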