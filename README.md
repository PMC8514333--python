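# nicuvalue

Value-based prioritization of clinician-driven tests and treatments
(CTTs) in multi-hospital NICU cohorts.

Neonatal intensive care for very-low-birth-weight (<1500 g) and very
preterm (<32 weeks) infants is costly, and much of the modifiable cost
sits in clinician-ordered tests and treatments — parenteral nutrition,
laboratory panels, imaging — whose use varies widely between hospitals
beyond what patient differences explain. `nicuvalue` implements a
prioritization framework for that problem: starting from encounter and
billing tables of a multi-hospital claims extract, it standardizes
charges to comparable costs, adjusts for patient case mix, quantifies
inter-hospital practice variation per CTT category, and ranks categories
by a composite score so that comparative-effectiveness and
quality-improvement effort can be pointed at the highest-yield targets.
It is written for health-services and neonatal outcomes researchers
working with administrative claims (or, out of the box, with the
package's own synthetic claims generator).

## The statistics at its core

For each CTT category *c* with hospital-level adjusted exposure
proportions p̂ₕ (hospital sizes nₕ, population proportion p̄) and adjusted
mean costs among exposed mₕ:

- **Exposure variability** — standard distances
  zₕ = (p̂ₕ − p̄) / √(p̄(1−p̄)/nₕ), with EV₍c₎ = SD(zₕ).
  Under pure sampling from one population EV ≈ 1.
- **Utilization variability** — UV₍c₎ = SD(mₕ)/mean(mₕ), the coefficient
  of variation of hospital mean costs.
- **Variability index** — VI₍c₎ = √((EV₍c₎/s₍EV₎)² + (UV₍c₎/s₍UV₎)²),
  a standardized Euclidean distance (s₍·₎ are across-category SDs).
- **Prioritization score** —
  PS₍c₎ = √((C₍c₎/s₍C₎)² + (E₍c₎/s₍E₎)² + (VI₍c₎/s₍VI₎)²) over total
  adjusted cost C, proportion exposed E, and VI, equally weighted.

Around these sit: a median-of-hospital-medians **cost index** that
replaces hospital-specific charges with standardized unit costs; an
LOS-based severity score (**NICU-SOI**, the Winsorized mean NICU length
of stay of a stay's APR-DRG relative to the overall mean, mortalities
excluded); random-intercept mixed models giving the **ICC** — the share
of covariate-adjusted log-cost variance attributable to hospitals; and
indirect standardization (observed/expected × pooled mean) for
hospital-level adjusted estimates.

## Worked example

```bash
python examples/rank_published_categories.py
```

prints, from the packaged published 36-category summary table:

```
re-derived cost ranks match the published ranks: True
top 3 by cost: $111,373,888 (39.6% of all-category cost)
top 10 by prioritization score: $185,820,181 (66.1% of all-category cost)
single costliest category: $58,411,076 (20.8% of all-category cost)
```

i.e. three categories (parenteral nutrition, chemistries,
anticoagulants) carry ~40% of all CTT-related cost, and the ten
top-prioritized categories carry two-thirds of it. The other examples
simulate a hospital system end to end (`simulate_and_prioritize.py`),
show the cohort exclusion cascade (`exclusion_cascade.py`), and recover
a planted ICC (`icc_recovery.py`). A thin CLI mirrors the pipeline:

```bash
nicuvalue run-all --workdir out --seed 7 --n-hospitals 8 --patients 150
```

writes every artifact (cohort, exclusion log, cost index, per-category
summary with EV/UV/VI/PS and ranks, hospital outlier report) as CSV.

## Layout

- `src/nicuvalue/` — `schemas`/`io` (table schemas, CSV round-trip),
  `simulate` (synthetic claims with planted ground truth), `cohort`
  (exclusion cascade), `costing` (cost index, standardization,
  resource-intensive decile), `severity`/`models` (NICU-SOI, mixed
  models, ICC, indirect standardization), `variability` (EV/UV/VI/PS,
  ranks, outliers), `pipeline`/`cli` (artifact orchestration),
  `reference` (published summary table), `evaluation` (recovery
  experiments).
- `docs/methods.md` — model assumptions, parameter choices, numerical
  conventions, limitations.
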