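"""Validation study: recover the generator's ground truth from raw tables.

With all noise off the pipeline inverts the forward model exactly; with
realistic noise the estimates stay unbiased, shown here for the allocation
fraction over replicate campaigns.
"""

import numpy as np

import symflux as sf

design, truth = sf.scenario_liverwort_co2(noise=False)
campaign, _ = sf.simulate_campaign(design, truth, seed=1)
rec = sf.recover_truth(campaign).set_index(["species", "co2_ppm"])
err = max(
    abs(rec.loc[key, "allocation_fraction"] - cell.allocation_fraction)
    / cell.allocation_fraction
    for key, cell in truth.cells.items()
)
print(f"noiseless: max relative error of recovered allocation fraction = {err:.2e}")

design, truth = sf.scenario_liverwort_co2(noise=True)
key = ("Treubia", 1500.0)
estimates = []
for seed in range(40):
    campaign, _ = sf.simulate_campaign(design, truth, seed=seed)
    rec = sf.recover_truth(campaign).set_index(["species", "co2_ppm"])
    estimates.append(rec.loc[key, "allocation_fraction"])
estimates = np.asarray(estimates)
print(
    f"noisy ({len(estimates)} campaigns): allocation estimate "
    f"{estimates.mean():.4f} +/- {estimates.std(ddof=1) / np.sqrt(len(estimates)):.4f} "
    f"(truth {truth.cells[key].allocation_fraction})"
)
print()
print(
    "The noiseless error is at machine precision: the pipeline is the exact\n"
    "inverse of the measurement model. Under Poisson counting noise, IRMS\n"
    "noise and 15% pot-to-pot variability the estimator stays unbiased."
)
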