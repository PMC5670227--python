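# reefstress

Cumulative marine heat-stress metrics, benthic survey scoring, and
permutation-based community statistics for regional coral-bleaching
assessments — plus a seeded synthetic-data generator so the full pipeline
is testable without field data.

## What it does

- **`reefstress.thermal`** — converts sub-daily temperature-logger records
  into daily means, anomalies against a site's maximum monthly mean (MMM),
  and rolling Degree Heating Day / Degree Heating Week statistics under two
  accumulation rules (`all_positive`: every positive daily anomaly counts;
  `noaa_ge1`: only anomalies ≥ 1 °C count). Incomplete days are flagged,
  contribute zero stress, and are reported as gaps; trailing windows shorter
  than the 84-day default are flagged partial. Reported DHW is rounded *up*
  to the next tenth (conservative for a risk index).
- **`reefstress.scoring`** — photoquadrat point counts over labelled
  substrate maps (stratified random points: `g×g` grid with `g = floor(√n)`,
  one point per sub-cell, remainder uniform), percent cover on an all-points
  or coral-points basis, transect-level mean ± SE summaries with transects as
  the replicate unit, and roving-diver colony tallies per health category
  (UB / M / S / D).
- **`reefstress.stats`** — from-scratch square-root transform, Bray-Curtis
  dissimilarity, one- and two-way PERMANOVA (sequential Type-I partition via
  Gower centering; unrestricted permutation of raw observations;
  p = (b+1)/(m+1)), Holm sequential-Bonferroni pairwise comparisons,
  covariance-matrix PCA, and Pearson χ² (Yates correction optional).
- **`reefstress.synth`** — seeded generators: seasonal/tidal/heatwave
  temperature series, and survey/roving data whose health states follow a
  cumulative-logit dose-response in accumulated DHW, with a per-habitat
  tolerance shift (intertidal communities bleach less at equal DHW).
- **`reefstress.pipeline` / CLI** — config-driven orchestration with JSON
  manifests (seed, options, SHA-256 per output).

## CLI

```sh
reefstress heat   --config config.yaml --out out/heat
reefstress survey --config config.yaml --out out/survey
reefstress stats  --config config.yaml --out out/stats --n-perm 9999
reefstress simulate --config config.yaml --out out/sim
reefstress demo   --out out/demo --seed 1 --n-perm 999
```

`demo` chains simulate → heat → survey → stats over five built-in synthetic
sites (heatwave-affected intertidal/subtidal pair, a satellite-style site
surveyed once, an unstressed site, and a temperate roving-survey site) and
finishes in seconds even at 9999 permutations.

A config is a YAML mapping with a `seed`, optional `options`
(`rule`, `window_days`, `n_perm`, `chi2_correction`, `cover_basis`,
`min_coverage`) and a `sites` list; each site carries its `mmm`, a
`logger_csv` path **or** a synthetic `scenario`, and `surveys` / `roving`
entries that either point at CSVs or carry `generate` blocks. See
`reefstress.pipeline.demo_config()` for a complete example.

### File formats (all plain text)

- logger CSV: `timestamp, temperature_c`
- point-score CSV: `quadrat_id, transect_id, site, date, point_index,
  category, genus, morphology, health`
- roving CSV: `site, location, date, colony_id, diameter_cm, health`
- abundance CSV (wide): `site, habitat, time, transect_id` + one column per
  genus_health class
- quadrat maps: JSON region lists (rect + label)

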