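"""Project a state's population and size the MCH target groups.

Builds the Kaduna-like profile, compounds the census base forward nine
years, and applies the 5% / 20% pregnant and under-five fractions, plus the
63% below-poverty-line subset.
"""

from uhc_feasim import DemographyParams, derive_targets, project_population, vulnerable_subset
from uhc_feasim.presets import get_state_preset

params = DemographyParams()
profile = get_state_preset("Kaduna").profile

population = project_population(profile.census_population, profile.growth_rate, params.n_years)
targets = derive_targets(population, params)
vulnerable = vulnerable_subset(targets, params.vulnerable_fraction)

print(f"census base ({params.base_year}):        {profile.census_population:,d}")
print(f"projected population ({params.target_year}): {float(population):,.0f}")
print(f"pregnant women (5%):          {targets.pregnant_women:,d}")
print(f"under-five children (20%):    {targets.under_five:,d}")
print(f"all MCH beneficiaries:        {targets.all_mch:,d}")
print(f"vulnerable subset (63%):      {vulnerable.all_mch:,d}")
print()
print("These are the head counts the benefit package must cover in the")
print("target year; the vulnerable subset is the below-poverty-line group.")
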