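"""Generate synthetic facility registers and recover the configured costs.

Emits a Kaduna-like bundle of facility ledgers (visit registers, drug
dispensing, salaries, overheads, capital inventories), then runs the
costing pipeline on them to recover the configured per-visit unit costs.
"""

from uhc_feasim.costing import state_unit_component_costs
from uhc_feasim.synthetic import generate_state_bundle

bundle = generate_state_bundle("Kaduna", seed=42, n_facilities=50, noise_cv=0.1)
recovered = state_unit_component_costs(bundle.ledgers)
configured = {"capital": 43.9, "personnel": 676.5, "overhead": 9.7}

print(f"{len(bundle.ledgers)} facilities, noise CV 0.1, MCH weight {float(bundle.mch_weight)}")
for comp, target in configured.items():
    got = float(recovered[comp])
    print(f"{comp:10s} configured {target:8.1f}  recovered {got:8.2f}  "
          f"error {100 * abs(got / target - 1):.2f}%")
print(f"{'drugs':10s} recovered {float(recovered['drugs']):8.2f} per MCH visit")
print()
print("Recovery errors shrink as facilities are added or noise is reduced;")
print("at zero noise the pipeline returns the configured targets exactly.")
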