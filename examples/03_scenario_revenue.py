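"""Build each scenario's available revenue from the BHCPF allocation rules.

The BHCPF is 1% of the Consolidated Revenue Fund (38.555bn ₦), split
NHIS 50% / NPHCDA 45% / FMOH 5% and shared equally across 37 units
(36 states + FCT). Sub-scenarios vary the BHCPF fraction (50/70/95%) and a
25% counterpart-funding gross-up.
"""

from uhc_feasim import FundAllocation, scenario_revenue, state_share
from uhc_feasim.money import fmt_naira

alloc = FundAllocation()
print(f"NHIS (50%) state share:   {fmt_naira(state_share(alloc, '0.50'))}")
print(f"NPHCDA (45%) state share: {fmt_naira(state_share(alloc, '0.45'))}")
print()
for sid in ("1a", "1b", "1c", "1d", "1e", "1f"):
    print(f"scenario {sid}: available {fmt_naira(scenario_revenue(sid, alloc)):>14s}")
print()
print("Naira available per state per year. Scenarios d-f gross the share up")
print("by the 25% state/LGA counterpart rate; the share is divided by 37")
print("before rounding, so amounts are exact to the Naira at display.")
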