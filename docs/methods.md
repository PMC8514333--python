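# Methods

## Problem and pipeline

The package quantifies how much of the cost of clinician-driven tests
and treatments (CTTs) in NICU care is carried by each category, how many
patients each touches, and how much hospitals differ in using it once
patient mix is accounted for — then combines the three into a ranking.
The pipeline stages are: cohort construction → charge-to-cost
standardization → severity scoring and risk adjustment → variability and
prioritization. Every stage exchanges plain CSV tables so runs are
auditable and restartable.

## Cohort construction

The analytic population is very-low-birth-weight (<1500 g) and/or very
preterm (<32 completed weeks) infants, identified from discrete
birth-weight/gestational-age fields, with a diagnosis-code fallback when
both are missing. The exclusion cascade runs in a fixed order — not
VLBW/VP; pre-viable (GA < 22 weeks or BW < 400 g); admitted after 1 day
of age (day 0 and day 1 admissions stay); congenital-anomaly codes;
data-entry-error screens; hospitals left with fewer than 100 eligible
patients — and each encounter is counted at its first failing rule, so
the log doubles as a study flow diagram. The anomaly and VLBW/VP code
lists shipped as defaults are synthetic placeholders aligned with the
generator; real analyses must supply curated lists via `CohortConfig`.
The data-error screens are likewise config-supplied predicates,
defaulting to LOS > 400 days and birth weight more than 4 SD above the
gestational-age-specific mean (an approximate built-in BW-by-GA
reference table). Utilization is restricted to days with a NICU bed
charge so costs from other units never enter.

## Cost standardization

Charges are converted to standardized costs in three steps: divide
charges by a hospital-level regional wage index (identity when not
supplied); estimate each billing item's unit cost as the median across
hospitals of the hospital-level median of charge/units ("median of
hospital medians" — robust to hospital volume imbalance; the even-count
median is the midpoint of the two central values); then price every line
as units × indexed unit cost × inflation multiplier for its calendar
year (identity when no inflation table is supplied). Because the index
is shared, a hospital's own markup cancels and two hospitals with
identical utilization get identical costs. Exposure to a category is at
least one charge line on at least one NICU day. Resource-intensive stays
are the top decile of total CTT cost by a rank rule — sort ascending,
flag the top N − floor(0.9·N), ties broken by stable encounter-id order —
which reproduces the published 23,488/2,610 split at N = 26,098 exactly.
Currency is kept at full float precision internally and rounded only in
report outputs.

## Severity and risk adjustment

Severity is case-mix based: each APR-DRG's NICU-SOI relative weight is
its mean NICU length of stay divided by the overall mean, computed on a
mortality-excluded reference population with LOS Winsorized at the
5th/95th percentiles. Winsorization uses nearest-rank percentiles (the
ceil(p·n)-th order statistic), a deterministic convention chosen for
bit-reproducibility. The reference population defaults to the full
generated NICU population rather than the analytic cohort, and the
reference-weighted mean weight is exactly 1.

Two patient-level models carry the adjustment. A random-intercept
logistic model (variational Bayes fit; odds ratios as exp of posterior
mean ± 1.96 SD) relates resource-intensive stays to the demographic
covariates (sex, GA and BW category, race/ethnicity, admission source,
admission age, insurance, income quartile, disposition) plus NICU-SOI,
against fixed reference levels. A linear mixed model on log(cost + 1)
with a random hospital intercept yields the variance split
ICC = σ²ₕ/(σ²ₕ + σ²ₑ); the log scale is what makes the additive split
meaningful for right-skewed costs, and the +1 offset admits zero-cost
stays. Degenerate single-hospital data fall back to fixed-effects fits
with σ²ₕ reported at the zero boundary and a warning; non-convergence
raises a diagnostic error after optimizer fallbacks rather than
returning silent output.

Hospital-level "adjusted" estimates use indirect standardization: a
pooled fixed-effects-only model supplies each patient's expected
outcome, and the hospital's adjusted value is (observed/expected) ×
pooled mean. With no covariate signal this reduces exactly to the
observed value, which is what makes the adjustment testable against the
generator's unconfounded default. The construction is calibration
preserving in the expected-count-weighted sense: Σₕ Eₕ·adjustedₕ / Σₕ Eₕ
equals the pooled mean whenever all hospitals are retained, an identity
inherited from GLM residuals summing to zero. For the hospital outlier
report (medians against patient-level quartiles) the patient-level
analog is additive — cost − expected + pooled mean — which preserves the
distribution shape that medians and quartiles are taken over.

## Variability and prioritization

Per category, exposure variability is the sample SD (n−1 throughout) of
binomial standard distances zₕ = (p̂ₕ − p̄)/√(p̄(1−p̄)/nₕ); the sampling-SE
denominator makes EV ≈ 1 the "no real variation" baseline. The raw
cohort hospital sizes enter the SE. Utilization variability is the CV of
adjusted hospital mean costs among exposed patients, hospitals
unweighted. Hospitals with exposure rates above 4× or below ¼ of the
population rate are dropped from that category's calculation (strict
inequalities; billing-pattern artifacts, not practice variation).
Across-category standardizing SDs for the variability index and the
prioritization score are computed after that filter, on the final
included category set. A component with zero across-category SD
contributes nothing to a distance (warned) so small simulated tables
stay computable. Ranks are descending competition ranks (ties share the
smaller rank, next rank skipped). Outlier hospitals are those whose
median adjusted per-patient cost lies strictly above the population
third quartile or below the first (linear-interpolation quartiles of the
patient-level distribution), reported for total cost and per billing
group.

## Synthetic claims generator

The generator emulates the hierarchical structure of a multi-hospital
claims extract, not any real hospital system. Defaults: 40 hospitals ×
650 patients, six CTT categories with exposure/cost scales resembling
common NICU items, demographic marginals mirroring a published VLBW/VP
cohort, and planted nuisances (3% anomaly codes, 2% late admissions, 1%
pre-viable, 0.5% data errors, 10% of stays with trailing non-NICU days,
2% code-only VLBW/VP identification) so every exclusion rule is
exercised. Per category, exposure is Bernoulli on the logit scale with a
hospital random intercept (SD τ); exposed patients draw a log-normal
cost μ·exp(v_h + a_h + η_i) with a per-category hospital effect v_h
(SD ω), a shared hospital log-cost effect a_h, and a patient factor η_i
(SD 0.9) shared across categories; costs are spread over random NICU
days by normalized Gamma shares (CV 0.6) so patient totals are conserved
exactly. Charges are true costs times a hospital markup, log-normal
(SD 0.25) re-centred to exact unit median so that median-based
standardization cancels markups exactly rather than only in expectation.
The shared a_h is solved from the target between-hospital share ρ of
log-total-cost variance via σ²ₕ = ρ/(1−ρ)·σ²ₑ with σ²ₑ the patient-factor
variance; the default ρ = 0.277 mirrors the reported inter-hospital
share for total CTT cost, and `SimConfig.icc_scenario` zeroes τ and ω
and saturates exposure so the planted share is exact. One RNG stream per
hospital is derived from the master seed, making output byte-identical
for a fixed seed and independent of iteration order.

What the generator does *not* emulate: diagnosis-code co-occurrence,
correlation between demographics and resource use (covariates are
independent of exposure/cost by default — the `confounded` flag adds a
gestational-age effect when adjustment should have work to do),
per-category patient-level noise beyond the shared factor, seasonal or
secular trends, and real charge-master heterogeneity. Passing recovery
tests therefore demonstrates estimator correctness under the assumed
hierarchy, not performance on real claims.

## Problem sizes and numerical conventions

Recovery experiments run at 40 hospitals × 650 patients (the cohort
scale the framework targets) for ICC recovery and the EV null
calibration, and at 40 × 250 over a 4-level τ/ω grid × 10 seeds for
rank-monotonicity, sizes at which the variance-component sampling noise
is the visible limit (a 40-group variance estimate has CV ≈ √(2/39) ≈
23%, so single-replicate fitted ICCs scatter roughly ±0.05 around the
planted value and replicate means are used). The pooled-exposure
convergence check uses 260 × 100 so both the hospital-effect average and
the Bernoulli draws are in their asymptotic regime at the same total n.
Exact oracles (standardization identities, brute-force VI/PS/ranks,
Winsorization) are asserted at 1e-9 or tighter; stochastic recoveries at
the tolerances stated above. Expected exposure under a random intercept
is computed by 61-node Gauss–Hermite quadrature.

## Known limitations

The published per-category estimates (odds ratios, EV/UV/VI/PS values,
hospital medians) derive from a proprietary claims source and are not
reproducible here; the packaged published summary table supports
arithmetic cross-checks and examples only. The logistic GLMM uses a
variational approximation, whose interval calibration is checked
empirically (≥90% null coverage) rather than guaranteed; the cost model
ICC is on the log scale only. The adjustment mechanics (indirect
standardization with fixed-effects expectations) are one defensible
choice among several the framework's description leaves open; results
that depend on the choice reduce to observed values under the null
either way.
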