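"""Simulate one labelling campaign and quantify per-pot isotope fluxes.

Generates a 2 species x 2 CO2 x 10 pot campaign (Poisson counting noise,
IRMS noise, 15% between-pot biological CV), writes its raw CSV tables the
way a lab would record them, reads them back, and runs the quantification
pipeline.
"""

import tempfile

import symflux as sf

design, truth = sf.scenario_liverwort_co2(noise=True)
campaign, _ = sf.simulate_campaign(design, truth, seed=42)

# Round-trip through the on-disk formats (design.yaml + three CSV tables).
with tempfile.TemporaryDirectory() as d:
    sf.write_campaign(campaign, d)
    campaign = sf.read_campaign(d)

flux = sf.quantify_campaign(campaign)
cols = [
    "pot_id",
    "core_treatment",
    "total_c_fixed_g",
    "c_to_fungus_ng",
    "pct_allocation",
    "p33_mass_ng",
    "n15_mass_ng",
]
print(flux[cols].head(8).to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print(
    "Each row is one pot: total carbon fixed during the 14CO2 pulse (g), the\n"
    "gross carbon recovered in its labelled mesh core (ng) and the percent of\n"
    "fixed carbon that represents, plus the 33P and 15N the plant received\n"
    "(ng). Rotated-core pots show only the diffusive leak - compare their\n"
    "c_to_fungus_ng with static pots of the same treatment cell."
)
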