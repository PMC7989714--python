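# surveyharm

Worksheet-driven harmonization of multi-cycle cross-sectional health
surveys.

## The problem

Repeated cross-sectional surveys such as the Canadian Community Health
Survey (CCHS) re-release their microdata every cycle — and between
cycles variable names drift (`HWTAGBMI` → `HWTCGBMI` → `HWTDGBMI` for
body mass index), category structures change (15 age groups in
2001/2003, 16 from 2005 on), rounding conventions and inclusion rules
differ, and reserved numeric codes (6/7/8/9, 96/97/98/99, …) encode why
an answer is missing. Anyone pooling ten cycles for a trend analysis
ends up rewriting the same fragile recoding scripts.

`surveyharm` moves all of that knowledge out of code and into two
declarative CSV worksheets:

* **variables.csv** — one row per harmonized variable: name, labels,
  subject, section, type, units;
* **variable_details.csv** — one row per recode rule: which cycles it
  covers, the cycle-specific raw column names, the source value or
  closed interval `[a,b]` it matches (or the catch-all `else`), and the
  target — a category code, `copy`, a tagged-missing token `NA::a` /
  `NA::b`, or a derived-variable tag `Func::<name>`.

A generic engine then applies the worksheets to each cycle
(*recode with table*), computes derived indicators, and stacks the
transformed cycles into one pooled dataset.

Missing values stay meaningful throughout: `NA::a` marks *structurally
not applicable* (skip patterns, variables a cycle never collected),
`NA::b` marks *don't know / refusal / not stated*, and both propagate
through derived variables with `NA::a` dominating.

Derived indicators shipped in the registry:

* **BMI** `= weight / height²` (kg/m², 2 decimals, computed uniformly
  for all ages);
* **continuous age** = midpoint of the harmonized age group (80+ → 85);
* **pack-years** `= (cigarettes/day ÷ 20) × years smoked`, with years
  smoked taken as current age − age started (current smokers) or age
  quit − age started (former smokers), and never-smokers scoring 0;
* **ADL score** = count of five activities-of-daily-living items that
  need assistance (0–5);
* **binge drinking** = 5+ drinks on one occasion at least monthly.

The package ships demonstration worksheets (22 harmonized variables,
120 rules, 10 cycles 2001–2014) and a seeded synthetic-data generator
that emulates raw CCHS-style coding — including the 15- vs 16-category
age drift and per-cycle variable names — so the whole pipeline is
testable without any data access.

## Worked example

```python
import surveyharm as sh

ws = sh.load_demo_worksheets()
raw = sh.generate_cycle_fixture(sh.FixtureConfig("cchs2001_p", seed=1), ws)
table = sh.recode_with_table(raw, ws, print_notes=False)
print(table.n_rows, list(table.rows.columns[:3]))
print(table.labels["DHH_SEX"]["categories"])
```

prints

```
200 ['DHH_SEX', 'DHHGAGE', 'DHHGMS']
{1: 'male', 2: 'female'}
```

— 200 synthetic respondents whose raw 2001 columns (`DHHA_SEX`,
`DHHAGAGE`, `HWTAGBMI`, …) now carry harmonized names, labels and
tagged missing values. Pooling all ten cycles:

```python
tables = [sh.recode_with_table(
              sh.generate_cycle_fixture(sh.FixtureConfig(c, seed=1), ws),
              ws, print_notes=False)
          for c in ws.cycle_universe]
combined = sh.combine_cycles(tables)
print(combined.n_rows, combined.per_cycle_counts["cchs2001_p"])
```

prints `2000 200`: one pooled table spanning 2001–2014 with a
`survey_cycle` provenance column, where variables a cycle never
collected (the alcohol block in 2001) are filled with structural
`NA(a)`. The `examples/` directory walks through validation, recoding,
pooling and derived-variable recovery as runnable scripts.

## Command line

```sh
surveyharm validate                         # check the demo worksheets
surveyharm fixtures --out-dir fx --seed 1   # synthetic raw cycles
surveyharm recode fx/cchs2001_p.csv -o h01.csv --cycle cchs2001_p
surveyharm recode fx/cchs2003_p.csv -o h03.csv --cycle cchs2003_p
surveyharm combine h01.csv h03.csv -o pooled.csv
```

Flags: `--worksheets DIR` (your own worksheet pair), `--vars` (subset),
`--strict` (error on undocumented raw codes instead of tagging them
`NA::b`), `--no-notes`, `--numeric-output` (tagged missing as
value+tag column pairs), `--config run.yaml` (YAML mirroring the
flags). Output CSVs come with a JSON sidecar carrying labels, notes and
provenance (cycle id, worksheet checksums, engine version).

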