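# pupcensus

Estimation, assembly and trend analysis of fur seal pup census data, built
around the monitoring design used for the Australian fur seal
(*Arctocephalus pusillus doriferus*): capture-mark-resight (CMR) at large
colonies, replicate direct counts at small ones, aerial counts where access
is difficult, and 5-yearly species-wide censuses combined with per-colony
trend models.

## What it does

- **`pupcensus.survey_data`** — colony registry and survey CSV schemas,
  validation (closed region vocabulary, tally invariants, birth-season year
  assignment for Jan/Feb surveys), marking-fraction protocol checks.
- **`pupcensus.abundance`** — per-sub-area Chapman (bias-corrected
  Petersen) estimates `N = (M+1)(n+1)/(m+1) − 1` with the Seber/Chapman
  variance, dead-mark adjustment, sub-area aggregation, replicate
  direct-count averaging, and site-specific count-to-CMR conversion
  factors.
- **`pupcensus.census`** — per-season census tables, the early-mortality
  correction (live / (1 − 0.15) → pup production), the ×4.5
  pups-to-population multiplier, between-census percent-change columns and
  size-category classification.
- **`pupcensus.trends`** — per-colony negative-binomial (NB2, log link)
  GLMs of counts on year with alternating dispersion estimation,
  reliability classification (significance + deviance explained + theta),
  cubic-polynomial comparison fits, and metapopulation regressions
  (growth rate vs abundance, percent change by size category).
- **`pupcensus.simulate`** — seeded generators for colonies, mark-resight
  surveys, replicate counts with observer bias/noise, NB2 metapopulation
  trajectories, and Monte-Carlo recovery experiments (bias, RMSE, CI
  coverage).
- **`pupcensus.datasets`** — the published registry, census and trend
  tables used as regression-test inputs.

## CLI

All commands read a data directory containing `colonies.csv`,
`cmr_surveys.csv` and/or `count_surveys.csv` (schemas in
`pupcensus/survey_data.py`):

```sh
pupcensus validate data/
pupcensus estimate data/ --season 2017 -o estimates.csv
pupcensus census data/ --seasons 2013,2017 -o census.csv
pupcensus trends history.csv -o trends.csv
pupcensus simulate --config sim.yaml --seed 42 -o simulated/
```

Conversion factors (mortality fraction, population multiplier, per-colony
count conversion) can be overridden with a YAML config passed to
`pupcensus census --config`.

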