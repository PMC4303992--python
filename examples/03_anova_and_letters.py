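"""Factorial species x CO2 ANOVA with Tukey letter groupings.

Type II sums of squares (robust to lost pots), with Tukey-Kramer pairwise
comparisons over the four species x CO2 groups rendered as a compact letter
display: groups sharing a letter do not differ at P < 0.05.
"""

import symflux as sf

design, truth = sf.scenario_liverwort_co2(noise=True)
campaign, _ = sf.simulate_campaign(design, truth, seed=42)
table, reports, letters = sf.analyze_campaign(campaign)

print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print()
for response, disp in letters.items():
    print(f"{response}: {disp.letters}")
print()
print(
    "F ratios per model term (species, CO2, interaction) for each response;\n"
    "static pots only, since rotated pots measure the diffusion control.\n"
    "Large CO2-term F on the carbon responses with small F on the nutrient\n"
    "concentrations is the signature of carbon allocation rising under high\n"
    "CO2 without extra nutrient return."
)
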