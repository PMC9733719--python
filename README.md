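# penflow

Drinker-use analytics for group-housed finisher pigs: from water-flow sensor
pulses to hourly per-pig water use and activation counts, and from there to
diurnal-rhythm models, treatment and drinker-location effects, and
matched-pair analysis around tail-damage events.

Because no raw deployment data are deposited anywhere, the package ships a
first-class synthetic-data generator that emulates the statistical structure
the analysis models assume — square-root-scale Gaussian hourly observations
with a 3-harmonic diurnal pattern and linear age trend, pen/day random
intercepts, within-day AR(1) correlation, pen-level diurnal-shape and timing
heterogeneity, drinker-location preference with occasional switching,
injected sensor faults, and tail-damage events with elevated daytime use —
with ground-truth labels for everything it makes.

## Modules

| module | what it does |
| --- | --- |
| `penflow.synthetic` | pen rosters, pen/sensor hourly tables, pulse streams, sensor faults, tail-damage events |
| `penflow.ingest` | sensor calibration (pulses per liter), pulse-stream aggregation to hourly tables, pen-level sums |
| `penflow.cleaning` | per-batch harmonic OLS + 4-residual-SD outlier rule |
| `penflow.diurnal` | sqrt-scale 3-wave harmonic model of diurnal pattern and age trend; diurnal curves and daily totals |
| `penflow.periods` | low/peak1/peak2 segmentation, period × week × treatment mixed model with backward elimination, low-period share tests |
| `penflow.locations` | feeder-side vs opposite-side cup comparison (paired Wilcoxon) |
| `penflow.events` | matched case-control pairing, day −3…0 window summaries, pen-type × period × day × stocking model |
| `penflow.pipeline` / `penflow.cli` | configuration, CSV I/O, logging, run-everything entry point |

## CLI

Every stage is a subcommand of the `penflow` executable; global flags are
`--seed`, `--config` (YAML), `--out-dir` and `--log-level`:

```bash
penflow --seed 7 --out-dir out simulate
penflow --seed 7 --out-dir out clean --pen-hourly out/pen_hourly.csv --roster out/roster.csv
penflow --seed 7 fit-diurnal --pen-hourly out/pen_hourly_clean.csv
penflow --seed 7 --out-dir out run-all
```

`run-all` executes simulate → ingest → clean → diurnal fit → period,
location and event analyses, writes every intermediate table as CSV with a
schema header, and renders a Markdown report. All generator and model
parameters can be overridden from the YAML config; see
`penflow.config.PipelineConfig`.

## Statistical notes

- Both responses are square-root transformed before modeling and estimates
  are back-transformed by squaring.
- The harmonic model estimates fixed effects by OLS on the sine/cosine
  linearization with cluster-robust (by pen) standard errors; variance
  components and the AR(1) coefficient come from residual moments. This is
  the documented generalized-least-squares fallback for the full mixed
  likelihood: on the balanced hourly lattice the fixed-effect estimates are
  unbiased, as the noise-free and simulation tests verify.
- The period and event models are linear mixed models (statsmodels MixedLM)
  on cell means, reduced by backward elimination with likelihood-ratio tests
  under ML (marginality respected) and refit by REML.
- Subset tests in the location analysis carry no multiplicity correction.
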