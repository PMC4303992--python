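"""Chamber physics, DPM conversions and the per-pot 14C carbon budget."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import symflux as sf
from symflux import radiocarbon_flux as rc


@pytest.mark.parametrize(
    "dpm, bg, expected",
    [(60.0, 0.0, 1.0), (0.0, 0.0, 0.0), (6.0e6, 0.0, 1.0e5), (100.0, 40.0, 1.0), (10.0, 40.0, 0.0)],
)
def test_dpm_to_bq(dpm, bg, expected):
    assert sf.dpm_to_bq(dpm, bg) == pytest.approx(expected)


def test_chamber_carbon_mass_pure_co2():
    state = sf.ChamberState(101.325, 288.15, 0.003, 1.0)
    assert sf.chamber_carbon_mass(state) == pytest.approx(1.524, rel=1e-3)


def test_chamber_carbon_mass_ambient_mixing_ratio():
    state = sf.ChamberState(101.325, 288.15, 0.003, 440e-6)
    assert sf.chamber_carbon_mass(state) == pytest.approx(6.706e-4, rel=1e-3)


def test_chamber_carbon_vanishes_with_co2():
    tiny = sf.ChamberState(101.325, 288.15, 0.003, 1e-15)
    assert sf.chamber_carbon_mass(tiny) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        sf.ChamberState(101.325, 288.15, 0.003, 0.0)
    with pytest.raises(ValueError):
        sf.ChamberState(-1.0, 288.15, 0.003, 0.5)


def test_ideal_gas_molar_volume_at_stp():
    """Inverting the carbon mass for moles reproduces 22.414 l mol^-1 at STP."""
    state = sf.ChamberState(101.325, 273.15, 22.414e-3, 1.0)
    n = sf.chamber_carbon_mass(state) / (
        state.carbon_mass_fraction * state.co2_molar_mass
    )
    assert n == pytest.approx(1.0, rel=1e-3)


def test_chamber_mass_scaling(rng):
    """Linear in P, V and mixing ratio; inverse in T."""
    base = dict(pressure_kpa=100.0, temperature_k=290.0, chamber_volume_m3=0.003,
                co2_mixing_ratio=500e-6)
    m0 = sf.chamber_carbon_mass(sf.ChamberState(**base))
    for _ in range(3):
        k = rng.uniform(0.5, 2.0)
        for fld, direct in [("pressure_kpa", True), ("chamber_volume_m3", True),
                            ("co2_mixing_ratio", True), ("temperature_k", False)]:
            kwargs = dict(base)
            kwargs[fld] *= k
            m = sf.chamber_carbon_mass(sf.ChamberState(**kwargs))
            assert m == pytest.approx(m0 * (k if direct else 1 / k), rel=1e-12)


@pytest.mark.parametrize(
    "activity, scaling, supplied, expected",
    [(1.1e5, 1.0, 1.1e6, 0.1), (0.0, 7.0, 1.1e6, 0.0)],
)
def test_label_proportion(activity, scaling, supplied, expected):
    assert sf.label_proportion(activity, scaling, supplied) == pytest.approx(expected)


def test_label_proportion_clamps_with_warning():
    with pytest.warns(UserWarning, match="clamped"):
        assert sf.label_proportion(2.2e6, 1.0, 1.1e6) == 1.0
    with pytest.raises(ValueError):
        sf.label_proportion(1.0, 1.0, 0.0)


def test_carbon_in_pool_examples():
    m_c = 6.706e-4
    assert sf.carbon_in_pool(0.1, m_c) == pytest.approx(6.706e-5)
    assert sf.carbon_in_pool(0.0, m_c) == 0.0
    assert sf.carbon_in_pool(1.0, m_c) == m_c  # cannot fix more than the chamber holds
    with pytest.raises(ValueError):
        sf.carbon_in_pool(1.5, m_c)


@given(
    p1=st.floats(0, 1), p2=st.floats(0, 1),
    m1=st.floats(1e-6, 1e-2), m2=st.floats(1e-6, 1e-2),
)
def test_carbon_in_pool_monotone(p1, p2, m1, m2):
    if p1 <= p2:
        assert sf.carbon_in_pool(p1, m1) <= sf.carbon_in_pool(p2, m1)
    if m1 <= m2:
        assert sf.carbon_in_pool(p1, m1) <= sf.carbon_in_pool(p1, m2)


def test_peak_flux_time_examples():
    curve = sf.RespirationCurve([1, 9, 17, 21], [0.1, 2.0, 5.0, 3.2])
    assert sf.peak_flux_time(curve) == 17.0
    with pytest.warns(UserWarning, match="all-zero"):
        assert np.isnan(sf.peak_flux_time(sf.RespirationCurve([1, 3, 5], [0, 0, 0])))
    with pytest.raises(ValueError):
        sf.peak_flux_time(sf.RespirationCurve([1, 3], [0, 1]))
    # ties break to the earliest time
    assert sf.peak_flux_time(sf.RespirationCurve([1, 3, 5], [1, 2, 2])) == 3.0


def test_koh_trap_total_examples():
    traps = pd.DataFrame(
        {
            "dpm": [30.0, 30.0, 30.0],
            "background_dpm": 0.0,
            "aliquot_volume_ml": 1.0,
            "total_volume_ml": 2.0,
        }
    )
    assert sf.koh_trap_total(traps) == pytest.approx(3.0)
    assert sf.koh_trap_total(traps.iloc[:0]) == 0.0


def test_total_carbon_fixed_matches_simulated_truth(small_noiseless):
    """Noiseless simulate -> quantify reproduces each pot's true fixation."""
    _, _, campaign, truth_record = small_noiseless
    carbon = sf.total_carbon_fixed(campaign).set_index("pot_id")
    truth = truth_record.set_index("pot_id")
    np.testing.assert_allclose(
        carbon.loc[truth.index, "total_c_fixed_g"], truth["fixed_c_g"], rtol=1e-9
    )


def test_total_carbon_fixed_missing_tissue_gives_na(small_noiseless):
    design, _, campaign, _ = small_noiseless
    partial = sf.validate_campaign(
        design, campaign.pots, campaign.scint, campaign.tissue.iloc[1:]
    )
    with pytest.warns(UserWarning):
        carbon = sf.total_carbon_fixed(partial)
    assert carbon["total_c_fixed_g"].isna().sum() == 1


def test_label_conservation_noiseless(small_noiseless):
    """Supplied activity = tissue + core + respired + chamber residual, exactly."""
    design, _, campaign, truth_record = small_noiseless
    acts = rc.pool_activities(campaign).set_index("pot_id")
    truth = truth_record.set_index("pot_id")
    recovered = (
        acts["a_plant_bq"] + acts["a_core_bq"] + acts["a_respired_bq"]
    ) + truth["a_residual_bq"]
    np.testing.assert_allclose(
        recovered, design.c14_supplied_activity_bq, rtol=1e-9
    )


def test_recovered_pool_activities_match_truth(small_noiseless):
    _, _, campaign, truth_record = small_noiseless
    acts = rc.pool_activities(campaign).set_index("pot_id")
    truth = truth_record.set_index("pot_id")
    for est, true in [
        ("a_plant_bq", "a_tissue_bq"),
        ("a_core_bq", "a_core_bq"),
        ("a_respired_bq", "a_respired_bq"),
    ]:
        np.testing.assert_allclose(acts.loc[truth.index, est], truth[true], rtol=1e-9)


def test_derived_co2_constants_match_conventional_values():
    m_co2, frac = rc.derived_co2_constants()
    assert round(m_co2, 2) == sf.CO2_MOLAR_MASS
    assert round(frac, 5) == sf.CARBON_MASS_FRACTION_CO2
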