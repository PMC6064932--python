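# Methods

This note documents the model, its parameters and defaults, the synthetic
data generator, and the numerical and design choices behind `uhc_feasim`.

## Scope and structure

The pipeline has five stages — demography, costing, revenue, feasibility,
reporting — plus a synthetic facility-register generator. It models one
state-year at a time: no inter-year carryover, no disbursement timing, no
absorption constraints, no uncertainty intervals (sensitivity is pure
scenario enumeration), and no cohort-component demography.

## Demography

Populations compound geometrically from a census base:
`P_t = P_0 (1 + g/100)^n`, with `n = target_year − base_year` (defaults
2006 → 2015, so n = 9) and a single growth rate per state. Target groups
are fixed shares of the projected population: pregnant women 5%, under-five
children 20%, and a vulnerable (below-poverty-line) subset of 63% of any
group. The 63% default matches the national poverty headcount and every
published vulnerable-group figure for the three study states; it is a
configurable parameter (`DemographyParams.vulnerable_fraction`,
`vulnerable_subset(..., fraction=...)`) for analysts who prefer another
headcount ratio.

Rounding: each fraction is applied to the *unrounded* projection and
rounded half-up independently; the combined MCH count is the sum of the
rounded parts. Independently rounded published totals can differ from that
sum by one person, so `TargetBeneficiaries` tolerates a ±1 discrepancy on
construction and fixtures store published values verbatim.

The three state presets carry back-derived census bases (Imo 3,934,899;
Kaduna 6,113,502; Niger 3,950,248): the unique integer censuses whose
projections reproduce the published 2015 pregnant and under-five targets
exactly under this rounding scheme. LGA counts in the presets are the
states' administrative counts; nothing numeric depends on them.

## Costing

**Capital annualization.** Equivalent annual cost by the standard annuity
factor `C·r/(1 − (1+r)^−L)`, straight-line `C/L` in the `r → 0` limit.
Defaults: discount rate 3%/yr; useful lives building 30y, transport 10y,
medical equipment 5y, other 5y. All configurable (`CostingParams`); the
annuity factor at r=0 is handled as the exact limit, not a division by
zero.

**Attribution and unit costs.** Shared components (capital, personnel,
overheads) are attributed to MCH with the facility utilization weight
(MCH visits / all outpatient visits; 0.83 Imo, 0.85 Kaduna, 0.90 Niger in
the reference data) and divided by MCH visits. Pooling across facilities
uses the ratio-of-sums estimator (total attributable cost / total MCH
visits), which is what scaling average facility cost by the standard
facility count implies.

**Package composition.** The maternal drug part prices the pregnancy
pathway: full ANC drug course + facility delivery + postnatal care, plus
family planning and the three complication services (malaria in pregnancy,
hypertension, postpartum hemorrhage) weighted by utilization proportions.
The ANC price is interpreted as the per-pregnancy course; non-drug
components instead accrue per facility contact — ANC visits (default 4) +
delivery + PNC = 6 contacts. This per-course/per-visit split is a
documented interpretation (the alternative, per-visit ANC drugs, is a
matter of supplying a different price list); it reproduces the published
Imo and Kaduna full-package costs to within 1 ₦. The child package is
3 visits/year at the mix-weighted drug price plus per-visit components.
The per-beneficiary ("either mother or child") cost mixes maternal and
child at 0.2/0.8, the demographic composition of the target group.

**Exchange rate.** 305.5 ₦/US$ (display only, never stored), the rate
implied by the published Naira/US$ pairs.

## Service-mix calibration

Facility-level utilization mixes are not recoverable from aggregate
figures, so preset mixes are identified once against the per-state
drugs-only unit costs:

- Maternal: with the core pathway fixed, the optional-service weights take
  the minimum-norm solution `w = residual·p/(pᵀp)` — nonnegative whenever
  the target exceeds the core cost, and exact by construction.
- Child: weights over the five child services must be nonnegative and sum
  to one while matching the per-visit drug cost; we take the point of that
  affine slice closest to the uniform mix, with a clamp-and-resolve active
  set for nonnegativity (the pneumonia weight binds at zero for Imo- and
  Kaduna-like targets), followed by an exact rational re-fit of the two
  extreme-price weights so the mix reproduces the target identically.

These are identification conventions, not behavioural estimates: any mix on
the feasible slice reproduces the same package cost.

## Revenue

State share of a BHCPF fraction: `CRF1% · f / 37` with CRF1% =
38,555,000,000 ₦ and the NHIS/NPHCDA/FMOH split 50/45/5. Scenario letters
a–f set `f ∈ {0.50, 0.70, 0.95}` without (a–c) and with (d–f) a 25%
counterpart gross-up; families 1/2/3 set the funded component set
(drugs-only / +overheads / all components), with family 3 also drawing on
state and LGA PHC budgets and facility IGR. The 70% case treats the 20%
NPHCDA drugs earmark as a plain revenue fraction — no separate earmark
accounting exists in the scheme definition.

Counterpart funding defaults to `rate × scenario BHCPF revenue`, the
convention the scenario definitions and result tables follow. The
alternative reading (rate applied to the NPHCDA 45% component) is
available as `CounterpartBase.NPHCDA_COMPONENT`.

## Feasibility

`required = unit_cost × targets` on the unrounded unit cost;
`gap = available − required` exactly; `additional% = −100·gap/available`
(surpluses print as negative percentages); `lives = ⌊available/unit⌋` with
the unrounded unit — a fractional person cannot be covered. The published
tables mix two lives-covered conventions (floored unrounded ratio vs.
rounded-display inputs); regression tests accept either within one person.
The minimum-CRF solve is the closed form
`x = required · n_units / (fraction · CRF1%)`, reported with its ceiling.

## Exact arithmetic and rounding

Monetary chains are `fractions.Fraction` end to end; the 37-way fund split
is the only step producing a repeating decimal and stays rational until
display. Display rounding is half-up (half away from zero, the spreadsheet
convention). Consequences: `gap ≡ available − required` holds identically
with no float drift, and regenerated tables match published cells exactly
for available amounts and percentages, within 1 ₦ for gaps (published gap
cells embed an unrecoverable intermediate-rounding path), and within one
person for lives covered. Known transcription inconsistencies in the
reference figures (one vulnerable-group gap cell; the Imo personnel total;
the Niger full-package units) are flagged in
`uhc_feasim.reference.KNOWN_ERRATA` and excluded from numeric regressions.

## Synthetic registers

The generator emulates what facility data collection yields: monthly visit
counts per service (gamma-Poisson with mean-CV parameterization), drug
line items priced from the price list with multiplicative lognormal jitter
(mean 1, CV `noise_cv`), and salary/overhead/capital totals constructed so
the pipeline's expected per-visit unit costs equal the configured targets.
Capital requirements are split over asset categories (building 50%,
equipment 30%, transport 15%, other 5%) and converted to replacement costs
through the inverse annuity factor, so annualization recovers the target.

At `noise_cv = 0` recovery is exact by construction; at `noise_cv = 0.1`
with 50 facilities the pooled estimator is typically within ~3% of the
targets (the max error over three components occasionally brushes that
level, as a mean-one CV-0.1 noise average over 50 facilities implies).
State-like bundles use the published per-facility annual maternal/child
utilization (817/3,658 Imo, 4,690/8,671 Kaduna, 2,623/5,555 Niger)
distributed over services by the calibrated mixes.

What the generator does **not** emulate: patient-level episodes,
seasonality, inter-facility correlation, price inflation, or missing and
misreported registers. Passing recovery tests therefore demonstrate the
pipeline's estimators are consistent under the model's own assumptions,
not robustness to real-world register quality.

## Problem sizes

The default test and acceptance runs use desk-scale inputs: three states,
four published scenario tables (48 rows), 50 synthetic facilities for
recovery checks, and 12 for end-to-end synthetic runs. The whole suite
runs in a few seconds on one CPU.

## Known limitations

- Single growth rate per state; no age structure or migration.
- Complication-service incidence is an identification convention, not an
  epidemiological estimate.
- Scenario-3 "other revenue" is a single aggregated block per state; its
  state/LGA/IGR decomposition is not separately validated.
- Costs and revenues are at 2015 levels with no inflation adjustment.
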