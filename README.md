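# uhc-feasim

Financial-feasibility modelling of Nigeria's **Basic Health Care Provision
Fund (BHCPF)** for a basic maternal-and-child-health (MCH) benefit package.

The BHCPF equals at least 1% of the Consolidated Revenue Fund (CRF) of the
Federation and is allocated through the NHIS (50%), the NPHCDA (45%) and the
FMOH (5%), each portion shared equally across the 36 states and the FCT.
This package answers the planning question health-financing analysts face:
*can that revenue pay for a defined MCH benefit package for every pregnant
woman and under-five child in a state — and if not, by how much does it fall
short?* It is written for health economists and ministry analysts, as a
Python library with a thin `uhc-feasim` CLI.

## Model

For a state *s* in target year *t*:

- **Demography.** Population projected geometrically,
  `P_t = P_2006 · (1 + g_s/100)^(t−2006)`; targets are pregnant women
  `0.05·P_t`, under-five children `0.20·P_t`, and the below-poverty-line
  subset `0.63 ×` any group.
- **Costing.** Bottom-up from facility ledgers: capital annualized with the
  annuity factor `C·r / (1 − (1+r)^−L)` (default `r = 3%`); shared costs
  (capital, personnel, overheads) attributed to MCH by the facility
  utilization weight `w = MCH visits / all visits` and divided by MCH visits
  into per-visit unit costs. The package cost per pregnant woman is the drug
  cost of the pathway (ANC course, facility delivery, PNC, plus family
  planning and complications weighted by utilization) plus per-visit
  components over 6 contacts; per child it is 3 visits at the mix-weighted
  drug price plus components. The per-beneficiary cost mixes the two,
  `0.2 · maternal + 0.8 · child`.
- **Revenue.** A scenario takes a BHCPF fraction `f ∈ {0.50, 0.70, 0.95}` of
  the state share `CRF1% · f / 37`, optionally grossed up by a 25%
  counterpart rate, optionally plus state/LGA PHC budgets and facility IGR.
- **Feasibility.** `required = unit_cost × targets`,
  `gap = available − required`, `lives = ⌊available / unit_cost⌋`,
  `additional% = −100 · gap / available`; plus the minimum CRF percent
  `x = required · 37 / (0.5 · CRF1%)` that would cover the largest state
  requirement.

All monetary chains use exact rational arithmetic (`fractions.Fraction`), so
row identities hold to the Naira and rounding happens once, at display
(half-up). A synthetic-register generator emulates facility cost ledgers and
visit registers whose aggregation recovers configured unit costs, so every
stage is testable without field data.

## Worked example

```python
from uhc_feasim import FundAllocation, scenario_revenue, state_share
from uhc_feasim.money import fmt_naira
from uhc_feasim.reporting import reference_rows

alloc = FundAllocation()
print(fmt_naira(state_share(alloc, "0.50")))      # 521,013,514
print(fmt_naira(scenario_revenue("1f", alloc)))   # 1,237,407,095

(row,) = reference_rows(["1f"], ["Kaduna"], ["child"])
print(fmt_naira(row.gap), row.lives_covered)      # 688,555,020 3,596,768
```

The first two numbers are one state's annual NHIS share of the fund and the
best-case drugs-only revenue (95% of the BHCPF plus 25% counterpart). The
last line shows that under that scenario Kaduna's child package runs a
688.6m ₦ surplus and could cover about 3.6m children — while the same
scenario leaves every combined mother-and-child row in deficit
(`examples/04_feasibility_tables.py` prints the full tables).

Each script in `examples/` exercises one capability: beneficiary projection,
package unit costs, scenario revenue, feasibility tables, synthetic
registers, and the minimum-CRF solve. The CLI mirrors them, e.g.
`uhc-feasim report`, `uhc-feasim synth --state-like Kaduna --seed 42`,
`uhc-feasim run -c config.yaml`.

## Layout

- `src/uhc_feasim/demography.py` — projection, targets, vulnerable subset
- `src/uhc_feasim/costing.py` — annualization, allocation, package costs, ledger IO
- `src/uhc_feasim/revenue.py` — fund split, scenario presets, counterpart rules
- `src/uhc_feasim/feasibility.py` — gap calculus, lives covered, minimum-CRF solve
- `src/uhc_feasim/synthetic.py` — facility-register generator
- `src/uhc_feasim/calibration.py` — service-mix calibration
- `src/uhc_feasim/reference.py` — published three-state reference figures
- `src/uhc_feasim/reporting.py` — tables, long-format IO, pipeline driver
- `docs/methods.md` — model assumptions, parameters, numerical choices
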