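# growthdom

Growth-partitioning analysis for repeated forest inventories: the growth
dominance coefficient (DC), the size–growth relationship slope (SGR),
sample-size/size-range sensitivity experiments, a nested-plot drought
analysis with mixed-effect period models and Tukey letters, and
site/climate covariate screening with AICc model comparison — all driven
by a seeded synthetic stand generator so every stage is testable without
proprietary inventory data.

## What it computes

- **DC** — trees sorted ascending by size; with cumulative proportional
  size `s_i` and growth `Δ_i`, `DC = 1 − Σ (s_i − s_{i−1})(Δ_i + Δ_{i−1})`.
  Bounded in [−1, 1] for non-negative growth; 0 means growth proportional
  to size, > 0 means large trees over-contribute.
- **SGR** — OLS slope of proportional individual growth on proportional
  individual size (1 under proportional growth).
- Supporting quantities: basal area `π(d/200)²`, configurable power-law
  stem mass, per-hectare expansion weights for the two-circle nested
  design (200 m² for d ≥ 12 cm → 50/ha, 500 m² for d ≥ 36 cm → 20/ha),
  annualized basal-area increments, growth-period assignment (seven
  periods, 1984–1994 … 2020, spring measurements closing the previous
  growing season), classic Thornthwaite monthly PET with day-length
  correction, seasonal climate aggregates, greedy collinearity screening
  at |r| > 0.5, and AICc-ranked mixed-model comparison with Akaike
  weights and marginal/conditional R².

## Layout

| module | contents |
| --- | --- |
| `growthdom.partition_indices` | DC, SGR, basal area, stem mass, derived increments |
| `growthdom.synthetic_stands` | seeded stand/inventory/climate generators, drought scenarios |
| `growthdom.subsample_experiment` | subsampling sensitivity, largest-tree removal test |
| `growthdom.drought_pipeline` | interval building, per-period DC/BAI mixed models, Tukey letters, size/density slopes |
| `growthdom.climate_covariates` | Thornthwaite PET, seasonal aggregates, screening, AICc selection |
| `growthdom.io_cli` / `growthdom.cli` | delimited-text IO, config, manifests, CLI |

## CLI

```sh
growthdom simulate   --seed 1 --n-plots 20 --n-trees 30 --scenario default --out runs/sim
growthdom sensitivity --seed 1 --census runs/sim/census.csv --replicates 25 --out runs/sens
growthdom drought    --seed 1 --census runs/sim/census.csv --out runs/drought
growthdom climate    --seed 1 --climate climate.csv --sites sites.csv \
                     --dc-table runs/drought/dc_table.csv --out runs/climate
```

Every run writes a `manifest.json` (config echo, seed, input hashes,
versions); manifests are byte-identical for identical runs. Census tables
are delimited text with header
`plot_id,tree_id,census_date,dbh_cm,species,status` (ISO-8601 dates);
thresholds (≥ 8 trees per plot, beech-dominated at ≥ 50% basal-area
share, α = 0.05, …) live in a single YAML config overridable per flag.

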