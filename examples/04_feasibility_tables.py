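"""Regenerate the scenario-1 feasibility tables from published inputs.

For each state and beneficiary group: amount required (unit cost x
targets), amount available (scenario revenue), lives covered, gap/surplus,
and the additional aggregate funds needed as % of available.
"""

from uhc_feasim.reporting import ReportSpec, reference_rows, render_feasibility_table

rows = reference_rows(["1a", "1f"])
for sid in ("1a", "1f"):
    print(render_feasibility_table([r for r in rows if r.scenario_id == sid], ReportSpec()))

print("Negative gaps are shortfalls (additional % positive); surpluses print")
print("negative percentages. Scenario 1f is the best drugs-only case: 95% of")
print("the BHCPF plus 25% counterpart still leaves every ALL-MCH row short.")
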