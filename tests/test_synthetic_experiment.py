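"""Forward-simulator invariants: determinism, feasibility, truth recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import symflux as sf

TRUTH_FIELDS = [
    "total_fixation_g",
    "allocation_fraction",
    "respired_fraction",
    "diffusion_leak_fraction",
    "p_delivery_ng",
    "n_delivery_ng",
    "peak_time_h",
]


def test_noiseless_inverse_identity(small_noiseless):
    """With noise off the pipeline inverts the generator exactly."""
    _, truth, campaign, _ = small_noiseless
    rec = sf.recover_truth(campaign).set_index(["species", "co2_ppm"])
    for cell_key, cell in truth.cells.items():
        row = rec.loc[cell_key]
        for name in TRUTH_FIELDS:
            assert row[name] == pytest.approx(getattr(cell, name), rel=1e-9), name


def test_same_seed_identical_tables_different_seed_not(small_noisy):
    design, truth, _, _ = small_noisy
    a, ta = sf.simulate_campaign(design, truth, seed=5)
    b, tb = sf.simulate_campaign(design, truth, seed=5)
    pd.testing.assert_frame_equal(a.scint, b.scint)
    pd.testing.assert_frame_equal(a.tissue, b.tissue)
    pd.testing.assert_frame_equal(ta, tb)
    c, _ = sf.simulate_campaign(design, truth, seed=6)
    assert not a.scint["dpm"].equals(c.scint["dpm"])


def test_infeasible_fractions_rejected():
    design, truth = sf.scenario_liverwort_co2(noise=False, replicates_per_cell=2)
    bad = {
        k: dataclasses.replace(v, allocation_fraction=0.9, respired_fraction=0.3)
        for k, v in truth.cells.items()
    }
    with pytest.raises(sf.SimulationError, match="exceed"):
        sf.simulate_campaign(design, dataclasses.replace(truth, cells=bad), seed=0)
    bad = {k: dataclasses.replace(v, diffusion_leak_fraction=1.5) for k, v in truth.cells.items()}
    with pytest.raises(sf.SimulationError, match="outside"):
        sf.simulate_campaign(design, dataclasses.replace(truth, cells=bad), seed=0)
    with pytest.raises(sf.SimulationError, match="no truth"):
        sf.simulate_campaign(
            design, dataclasses.replace(truth, cells=dict(list(truth.cells.items())[:2])), seed=0
        )


def test_missing_cell_truth_and_unknown_noise_rejected():
    design, truth = sf.scenario_liverwort_co2(noise=False, replicates_per_cell=2)
    with pytest.raises(sf.SimulationError, match="counting_noise"):
        sf.simulate_campaign(design, dataclasses.replace(truth, counting_noise="gauss"), seed=0)


def test_allocation_recovery_under_poisson_noise():
    """Parameter-recovery: allocation estimate unbiased within 2 MC SE."""
    design, truth = sf.scenario_liverwort_co2(noise=True, replicates_per_cell=4)
    key = ("Haplomitrium", 1500.0)
    estimates = []
    for seed in range(60):
        campaign, _ = sf.simulate_campaign(design, truth, seed=seed)
        rec = sf.recover_truth(campaign).set_index(["species", "co2_ppm"])
        estimates.append(rec.loc[key, "allocation_fraction"])
    estimates = np.asarray(estimates)
    mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - truth.cells[key].allocation_fraction) < 2 * mc_se


def test_scenario_headline_pattern_noiseless():
    """The canned scenario reproduces the qualitative CO2 response pattern."""
    design, truth = sf.scenario_liverwort_co2(noise=False)
    campaign, _ = sf.simulate_campaign(design, truth, seed=1)
    ex = sf.summarize_exchange(sf.quantify_campaign(campaign))
    ex = ex.set_index(["species", "co2_ppm", "response"])["value"]
    for sp in design.species_labels:
        # absolute C transfer rises at 1500 ppm for both hosts
        assert ex[(sp, 1500.0, "net_c_to_fungus_ng")] > ex[(sp, 440.0, "net_c_to_fungus_ng")]
        # nutrient return does not rise with CO2
        assert ex[(sp, 1500.0, "net_p33_ng")] <= ex[(sp, 440.0, "net_p33_ng")] * (1 + 1e-9)
        assert ex[(sp, 1500.0, "net_n15_ng")] <= ex[(sp, 440.0, "net_n15_ng")] * (1 + 1e-9)
        # hence exchange efficiency does not increase at 1500 ppm
        assert ex[(sp, 1500.0, "p_for_c_efficiency")] <= ex[(sp, 440.0, "p_for_c_efficiency")]
        assert ex[(sp, 1500.0, "n_for_c_efficiency")] <= ex[(sp, 440.0, "n_for_c_efficiency")]
    # the Treubia-like species also raises its percentage allocation
    assert ex[("Treubia", 1500.0, "pct_allocation")] > ex[("Treubia", 440.0, "pct_allocation")]


def test_scenario_interaction_power():
    """The species x CO2 interaction in % allocation is detected in most
    noisy replicates at the scenario's effect sizes."""
    design, truth = sf.scenario_liverwort_co2(noise=True)
    hits = 0
    n_rep = 40
    for seed in range(n_rep):
        campaign, _ = sf.simulate_campaign(design, truth, seed=seed)
        _, reports, _ = sf.analyze_campaign(campaign)
        p = reports["% plant-fixed carbon allocated to fungus"].terms["species_x_co2"].p
        hits += p < 0.05
    assert hits / n_rep >= 0.8


def test_label_conservation_every_generated_campaign(small_noisy):
    """Poisson counting noise is unbiased: the recovered pool split still
    sums to the supplied activity in expectation (and exactly without noise)."""
    design, truth, campaign, truth_record = small_noisy
    from symflux.radiocarbon_flux import pool_activities

    acts = pool_activities(campaign).set_index("pot_id")
    t = truth_record.set_index("pot_id")
    total = (
        acts["a_plant_bq"] + acts["a_core_bq"] + acts["a_respired_bq"] + t["a_residual_bq"]
    )
    # single noisy campaign: within 1% of the supplied activity per pot
    np.testing.assert_allclose(total, design.c14_supplied_activity_bq, rtol=0.01)
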