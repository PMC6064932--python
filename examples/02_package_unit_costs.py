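"""Compose per-beneficiary benefit-package unit costs for one state.

Uses the reference drug price list with the calibrated service mixes, then
adds per-visit overhead/personnel/capital components for the wider cost
sets. The combined cost mixes maternal and child at 0.2 / 0.8.
"""

from uhc_feasim.money import fmt_naira, to_float
from uhc_feasim.presets import preset_unit_costs

RATE = 305.5  # Naira per US$

for component_set, pkg in preset_unit_costs("Imo").items():
    print(f"{component_set:16s} maternal {fmt_naira(pkg.maternal):>7s} "
          f"(${to_float(pkg.maternal / RATE):.1f})  "
          f"child {fmt_naira(pkg.child):>6s}  combined {fmt_naira(pkg.combined):>6s}")

print()
print("Naira per beneficiary per year. 'drugs_only' is the thin package the")
print("main scenarios fund; the wider sets add overheads, then personnel and")
print("annualized capital, per facility contact (6 maternal, 3 child).")
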