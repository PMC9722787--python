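# brackish

Estuarine water-quality, phytoplankton-community and fish-diet analysis
toolkit. It covers, as a tested reusable pipeline:

- **hydrography** — stratification parameter and mixing class from CTD
  salinity casts, Venice salinity zoning, along-axis isohaline position,
  and hilsa habitat-suitability screening;
- **plankton** — trichromatic chlorophyll-a, counting-chamber cell
  densities, community composition, Simpson diversity (D and 1/D);
- **electivity** — the odds-ratio diet electivity index
  `X = O / (1 + O)` with `O = (g/(1-g)) * ((1-a)/a)` comparing gut and
  water taxon proportions, overall and by fish size class;
- **trophic** — percentile-based indicator statistics (DIN, DIP, DSi,
  chlorophyll-a) and Good/Fair/Poor/Very-poor classification;
- **waterstats** — descriptive median/SE tables, paired Wilcoxon seasonal
  tests, Kruskal–Wallis spatial tests, a starred Pearson correlation
  matrix, and correlation-matrix PCA;
- **pufa** — season-averaged composition arithmetic and PUFA-weighted
  scoring of diet composition;
- **synthetic** — a fully seeded scenario generator producing the three
  CSV schemas with the seasonal/spatial structure the analysis assumes,
  so everything is testable offline.

## Data formats

Three tidy long-format CSVs (ISO-8601 dates, units implicit per schema):

- `water.csv`: `station_id, site_id, date, [season,] temperature,
  salinity, do, ph, no3_n, no2_n, nh4, po4_p, dsi, chla`
- `ctd.csv`: `station_id, date, axis_km, depth_m, salinity[, temperature]`
- `counts.csv`: `source, sample_id, fish_length_cm, fish_weight_g, genus,
  phylum, count`

When `season` is absent it is filled from the configurable month map
(default: Dec–Mar dry, Jul–Oct wet; other months are "transitional" and
excluded from seasonal tests). In `counts.csv` the season of a sample is
recovered from a `dry`/`wet` token in its `sample_id` (as produced by the
simulator).

## CLI

```sh
brackish simulate   --seed 42 --out data/            # write the three CSVs
brackish hydro      --ctd data/ctd.csv --iso 2 --out out/
brackish community  --counts data/counts.csv --out out/
brackish electivity --counts data/counts.csv --level phylum \
                    --size-bins 10,20,30,35 --correction none --out out/
brackish trophic    --water data/water.csv --season both --out out/
brackish stats      --water data/water.csv --out out/
brackish pufa       --composition out/composition.csv --out out/
brackish run-all    --seed 42 --out run/ [--config scenario.yaml] [--plots]
```

`run-all` executes every stage into one directory and writes
`manifest.json` (config hash, seed, per-stage outputs, warnings). A
scenario YAML may override any `ScenarioSpec` field, e.g.:

```yaml
n_fish: 40
rng_seed: 7
gut_total_range: [100, 300]
```

## Notes

- Rounding of reported percentages is decimal half-up and happens only at
  the reporting edge; all averaging uses unrounded inputs.
- The mixing classes use thresholds 0.1 / 1.0 on the stratification
  parameter; Venice class boundaries are half-open on the low side.
- Missing values are excluded pairwise (tests, correlations) or casewise
  (PCA); nothing is imputed.
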