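# nutriwarn

A pipeline for nutrient-profile warning-label analysis of packaged-food
product databases. It applies two front-of-package nutrient profile models —
a category-scoped model with 25 food categories and a non-nutritive-sweetener
override (SEARO), and a food/beverage-scoped model whose thresholds are gated
on added-ingredient declarations (Chilean Warning Octagon, Phase 3) — to
tabular product records, after running a reproducible exclusion cascade
(deduplication, label errors, category assignment, variety packs, baby food,
nutrient sufficiency, reconstitution to an "as consumed" basis).

The package also ships a seeded synthetic database generator (log-normal
nutrient amounts, ingredient flags correlated with amounts, configurable
missingness and planted exclusions), coverage calibration, and biased
industry-style subsampling for selection-bias experiments.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: printed-number
fidelity fixtures, engine-vs-brute-force oracle equivalence on 10,000 random
panels, and the biased-sampling behaviour checks.

## CLI

```sh
nutriwarn run --input products.csv --outdir out          # full pipeline
nutriwarn run --seed 1 --n-products 10000 --outdir out   # generator mode
nutriwarn run --models SEARO --nns-meets-any-only ...    # model/convention switches
nutriwarn generate --seed 1 --n-products 5000 --out db.csv
nutriwarn calibrate --targets targets.yaml --out db.csv  # hit coverage targets
nutriwarn validate-thresholds                            # scope/unit sanity
nutriwarn fixtures --outdir fx --scale 0.1               # canned cascade dataset
```

`run` writes the analyzable product set, the exclusion ledger (in cascade
order), the coverage report as CSV/text/JSON summary, per-product results,
and a manifest (config hash, seed, versions, ledger) that suffices to
reproduce the run. A YAML config can supply any flag (`--config cfg.yaml`);
flags win on conflict.

Threshold tables are plain CSV data (`src/nutriwarn/data/`), columns
`scope,nutrient,limit,unit,comparator,gate,label` — the engines are
model-agnostic, so alternative models can be dropped in without code changes.

## Layout

- `nutriwarn.taxonomy` — 25-category registry and the food/beverage split
- `nutriwarn.records` — nutrient panel, ingredient flags, product record types
- `nutriwarn.ingestion` — CSV reading, exclusion cascade, reconstitution, ledger
- `nutriwarn.engines` — data-driven threshold evaluation for both model families
- `nutriwarn.reporting` — coverage and 0/1/2/3+ label-distribution tables
- `nutriwarn.synthetic` — seeded generator, calibration, biased subsampling
- `nutriwarn.cli` — `nutriwarn` command
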