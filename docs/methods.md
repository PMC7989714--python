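# Methods

## The harmonization model

`surveyharm` treats survey harmonization as interpretation of a
declarative rule table rather than as bespoke code. A *worksheet set*
consists of a variable index (identity and metadata of each harmonized
variable) and a rule table in which every row maps, for a stated set of
survey cycles, one source condition to one target:

* source (`recStart`): a single category code, a closed numeric
  interval `[a,b]` with `a ≤ b`, the keyword `else`, or `NA` (an empty
  source cell);
* target (`recEnd`): a harmonized category code, `copy` (pass the
  source value through — used for continuous variables), a
  tagged-missing token, or `Func::<name>` invoking a registered
  derived-variable function.

Per-cycle raw column names are declared as `cycle::RAWNAME` entries
plus one bracketed default `[RAWNAME]`, which is how the model absorbs
name drift across cycles. Derived rows carry their harmonized inputs as
`DerivedVar::[A, B, …]`.

**Matching semantics.** A specific rule always beats `else`; `else`
applies only to values no other rule matches. Because the validator
rejects overlapping source specs, rule order is irrelevant — a property
the test suite checks by permuting rule rows. Code matching uses an
absolute tolerance of 1e-9 so float-typed CSV values compare reliably
against integer codes; interval bounds are inclusive with the same
tolerance. `NaN` source cells match only `NA` and `else`.

**Unmatched values.** Real survey files occasionally contain codes the
codebook never documented. By default the engine recodes them to
`NA::b` and emits a warning (lenient mode); `strict=True` raises
instead. Both behaviours are exposed because either can be the right
choice in a production pipeline.

## Tagged missing values

Two reasons for missingness are kept distinct end to end: `NA::a`
(structurally not applicable — a skip pattern, or a variable a cycle
never collected) and `NA::b` (don't know / refusal / not stated). The
reserved raw codes that encode these reasons (6 vs 7/8/9 for 1-digit
variables, 96 vs 97/98/99 for 2-digit, 996 vs 997/998/999 for 3-digit)
are written down as ordinary worksheet rules, not engine magic: the
engine stays generic and the worksheets carry the survey-specific
knowledge. In derived functions any tagged input yields a tagged
output, with `NA::a` dominating `NA::b`. In CSV output, tagged values
render as the literal strings `NA(a)`/`NA(b)`; with numeric rendering
each affected column splits into a numeric value column and a `__na`
tag column. Both renderings round-trip bit-exactly.

## Derived variables

Derived variables are computed after the row-level recode, in a
topologically sorted pass over their dependency graph (pack-years
consumes continuous age, which is itself derived); cycles in the graph
are a validation error. Registry functions and their conventions:

| function | definition | notes |
|---|---|---|
| `bmi_fun` | weight/height², 2 decimals | computed for all ages uniformly; heights outside (0.5, 2.5) m or weights outside (20, 300) kg → `NA::b` |
| `age_cont_fun` | midpoint of the harmonized age group | open-ended 80+ group → 85 years |
| `pack_years_fun` | (cigarettes/day ÷ 20) × years smoked | years = age − started (current) or quit − started (former); never-smokers → 0 |
| `adl_score_5_fun` | count of five items coded 1 | exactly five inputs required |
| `binge_drinker_fun` | 1 if 5+ drinks ≥ once/month else 2 | threshold = frequency codes 3–6 |

Design choices that were genuinely open, and the package's resolution:

* **Pack-years formula.** The standard epidemiological definition
  (one pack = 20 cigarettes) is used. Occasional smokers enter through
  their reported cigarettes/day; no separate treatment is attempted.
* **Never-smoker gate.** A confirmed never-smoker scores 0 pack-years
  even though the smoking-history questions are structurally skipped
  (`NA::a`) for them: the smoker-status input acts as a gate evaluated
  before generic missing-value propagation. A tagged *status* still
  propagates. This is the one scoped exception to blanket propagation,
  and it is what makes the variable usable — otherwise every
  never-smoker would be missing.
* **Top age midpoint.** The 80+ group needs a proxy age; 85
  approximates the conditional mean of that group and is overridable by
  passing explicit bounds.
* **BMI rounding.** Source cycles disagree (1 vs 2 decimals); the
  harmonized derived BMI keeps 2 decimals, the maximum precision any
  cycle ships.
* **Binge threshold.** "At least monthly" is the common
  operationalization in the CCHS literature; the scale itself carries
  no canonical cut.

## The demonstration worksheet set

The packaged worksheets cover 22 harmonized variables (socio-
demographic: sex, age group, continuous age, marital status, household
income; health behaviours: smoking status and history, pack-years,
5+ drinks frequency, binge flag; health status: height, weight, raw and
derived BMI, five ADL items and the ADL score) across 10 cycles,
2001–2014. Structural features worth knowing:

* The age variable declares 15 source categories for 2001/2003 and 16
  for 2005 onward (the 15–19 group splits into 15–17 and 18–19); the
  harmonized variable collapses both structures onto the common
  15-category set. Category boundaries are 12–14, 15–19, then 5-year
  groups to 75–79, then 80+.
* Sex and the ADL items are fully enumerated without an `else` rule —
  their declared domains are closed — which keeps the
  lenient/strict unmatched-value machinery reachable. Every other
  variable carries `else → NA::b`. The validator's coverage finding
  therefore fires only for continuous variables lacking a catch-all.
* The alcohol block is declared for 9 of the 10 cycles (absent in
  2001), exercising the pooled table's structural `NA::a` fill.
* The full worksheet content of the original 160-variable survey
  codebase is deliberately not ported; the demo set is a faithful
  structural model, not a data product.

## Pooling

`combine_cycles` stacks harmonized tables produced against the same
worksheet set. Row order is input order of tables then original row
order; total rows always equal the sum of the inputs. The provenance
column `survey_cycle` is reserved (collision is an error). Label
metadata is merged with conflict detection: one harmonized code, one
label, everywhere. Filtering the pooled table back to one cycle
reproduces that cycle's table exactly, restricted to the variables the
cycle collected.

## Synthetic data

The plain generator is entirely worksheet-driven: for each variable
applicable to the requested cycle it reads the declared source domain
and draws categorical codes uniformly over the valid codes, continuous
values uniformly within the `copy` interval, reserved missing codes at
`missing_rate` (default 0.05) and codes outside the documented domain
at `undocumented_code_rate` (default 0). Defaults emit 200 respondents
per cycle, mirroring the subsample size this kind of package ships for
demonstration. Same configuration, same bytes: all randomness flows
from `numpy`'s seeded generator keyed by (seed, cycle index, variable
stream).

The truth-paired generator additionally returns the latent truths —
exact age, height/weight (and hence true BMI), full smoking history
with its pack-years, 5+ drinks frequency, true ADL count — and encodes
them into raw codes the way the modelled survey would: age binned to
the cycle's 15- or 16-group structure, raw BMI rounded to 1 decimal in
2001/2003 and 2 decimals later, ADL counts spread over the five items.
It knows the demo variables' semantics and is specific to them.

What the fixtures do *not* emulate: realistic marginal distributions,
inter-variable correlations (beyond the deterministic consistency of
the truth-paired columns), survey weights, design effects, or item
nonresponse patterns that depend on respondent characteristics.
Passing tests therefore demonstrate that the *mechanics* of
harmonization are correct — not that any epidemiological estimate from
real data would be.

## Numerical and degenerate-input choices

* Harmonized columns are object-dtype pandas columns mixing Python
  numbers with tagged-missing markers; category codes are stored as
  `int` when integral.
* Zero-row inputs are legal everywhere and preserve full label
  metadata.
* Worksheet serialization is RFC-4180 CSV; a write→parse round trip is
  field-identical (checked, including via property-based tests).
* Problem sizes in the test and acceptance runs — 200-row fixtures per
  cycle, 1000–1200-row fixtures for the engine-vs-oracle comparison,
  400–500-row truth-recovery runs — are the package's chosen
  demonstration scale; every check is deterministic given its seed.

## Known limitations

* Survey weights, variance estimation and any sampling-design
  adjustment are out of scope; pooled analyses of real data need them.
* No imputation: a variable absent from a cycle stays structurally
  missing in the pooled table.
* SPSS/Stata ingestion is an extension point, not built in; inputs are
  CSV.
* The income variable is a raw category pass-through; no inflation or
  regional adjustment is attempted (that would require external
  reference tables).
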