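"""Net fungal transfer and carbon-for-nutrient exchange efficiency per cell.

Static-minus-rotated differencing removes the diffusion leak, leaving the
hyphal transfer; exchange efficiency is nutrient gained per unit carbon
allocated to the fungus (ng/ng), computed from the net cell means.
"""

import symflux as sf

design, truth = sf.scenario_liverwort_co2(noise=True)
campaign, _ = sf.simulate_campaign(design, truth, seed=42)
flux = sf.quantify_campaign(campaign)
ex = sf.summarize_exchange(flux)

show = ex[
    ex["response"].isin(
        ["net_c_to_fungus_ng", "pct_allocation", "net_p33_ng", "p_for_c_efficiency", "n_for_c_efficiency"]
    )
]
print(show.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
print()
print(
    "net_c_to_fungus_ng: hyphal carbon transfer per pot (diffusion removed).\n"
    "Both species move more absolute carbon at 1500 ppm CO2, but nutrient\n"
    "return does not rise with it, so P-for-C efficiency is highest at\n"
    "440 ppm - the fungus gets cheaper for the plant as CO2 falls."
)
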