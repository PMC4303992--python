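"""Carbon flux quantification from 14C scintillation counts.

The pulse-chase design supplies a known 14CO2 activity to a sealed chamber
holding one pot. The fraction of that label recovered in a pool (plant
tissue digest, labelled-core digest, KOH respiration traps) multiplied by
the total carbon mass the chamber's CO2 held gives the total carbon
(12C + 14C) routed into that pool:

    pool C = P_r * m_c,        P_r = pool activity / supplied activity,

with m_c from the ideal gas law,

    n = P * V_co2 / (R * T),   m_c = 0.27292 * n * 44.01 g,

where 0.27292 is the mass fraction of carbon in CO2. The printed chamber
constant 0.003 m^3 is, by default, interpreted as the chamber volume to be
multiplied by the treatment CO2 mixing ratio (440e-6 or 1500e-6); a config
switch treats it as the CO2 volume itself instead.

No quench or counting-efficiency correction is applied (background
subtraction only), and 14C decay over the <=24 h assay is ignored
(half-life 5730 yr).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    ATOMIC_MASS_C,
    ATOMIC_MASS_O,
    CARBON_MASS_FRACTION_CO2,
    CO2_MOLAR_MASS,
    DPM_PER_BQ,
    GAS_CONSTANT,
)
from .experiment_model import Campaign, ExperimentDesign

__all__ = [
    "ChamberState",
    "RespirationCurve",
    "derived_co2_constants",
    "dpm_to_bq",
    "chamber_carbon_mass",
    "label_proportion",
    "carbon_in_pool",
    "total_carbon_fixed",
    "peak_flux_time",
    "koh_trap_total",
    "pool_activities",
    "belowground_curve",
]


def derived_co2_constants() -> tuple[float, float]:
    """Recompute (CO2 molar mass, carbon mass fraction) from atomic masses.

    Returns the values implied by the standard atomic masses of C and O,
    against which the conventional rounded constants 44.01 g mol^-1 and
    0.27292 can be checked.
    """
    m_co2 = ATOMIC_MASS_C + 2.0 * ATOMIC_MASS_O
    return m_co2, ATOMIC_MASS_C / m_co2


@dataclass(frozen=True)
class ChamberState:
    """Ideal-gas state of the labelling chamber at pulse time."""

    pressure_kpa: float
    temperature_k: float
    chamber_volume_m3: float
    co2_mixing_ratio: float
    gas_constant: float = GAS_CONSTANT
    co2_molar_mass: float = CO2_MOLAR_MASS
    carbon_mass_fraction: float = CARBON_MASS_FRACTION_CO2

    def __post_init__(self) -> None:
        if self.pressure_kpa <= 0 or self.temperature_k <= 0:
            raise ValueError("pressure and temperature must be strictly positive")
        if self.chamber_volume_m3 <= 0:
            raise ValueError("chamber volume must be strictly positive")
        if not 0.0 < self.co2_mixing_ratio <= 1.0:
            raise ValueError("CO2 mixing ratio must lie in (0, 1]")
        if not 0.0 < self.carbon_mass_fraction < 1.0:
            raise ValueError("carbon mass fraction must lie in (0, 1)")

    @classmethod
    def from_design(
        cls,
        design: ExperimentDesign,
        co2_ppm: float,
        volume_interpretation: str = "mixing_ratio",
    ) -> "ChamberState":
        """Chamber state for one treatment.

        ``volume_interpretation='mixing_ratio'`` multiplies the chamber
        volume by ppm * 1e-6 to obtain the CO2 volume;
        ``'co2_volume'`` takes the configured volume as pure CO2.
        """
        if volume_interpretation == "mixing_ratio":
            x = co2_ppm * 1e-6
        elif volume_interpretation == "co2_volume":
            x = 1.0
        else:
            raise ValueError(f"unknown volume interpretation {volume_interpretation!r}")
        return cls(
            pressure_kpa=design.pressure_kpa,
            temperature_k=design.temperature_k,
            chamber_volume_m3=design.chamber_volume_m3,
            co2_mixing_ratio=x,
        )


@dataclass(frozen=True)
class RespirationCurve:
    """An ordered (time h, activity Bq) gas-sampling series for one compartment."""

    times_h: np.ndarray
    activities_bq: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        a = np.asarray(self.activities_bq, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "activities_bq", a)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and activities must be 1-d arrays of equal length")
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("sampling times must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("activities must be nonnegative")


def dpm_to_bq(dpm: float, background_dpm: float = 0.0):
    """Background-subtracted activity in Bq (60 DPM = 1 Bq; floor at zero)."""
    return np.maximum(np.asarray(dpm, dtype=float) - background_dpm, 0.0) / DPM_PER_BQ


def chamber_carbon_mass(state: ChamberState) -> float:
    """Mass of carbon (g) in the CO2 the labelling chamber holds.

    Ideal gas law with pressure in kPa converted to Pa; the CO2 volume is
    chamber volume times the mixing ratio.
    """
    n_mol = (
        state.pressure_kpa
        * 1e3
        * state.chamber_volume_m3
        * state.co2_mixing_ratio
        / (state.gas_constant * state.temperature_k)
    )
    return state.carbon_mass_fraction * n_mol * state.co2_molar_mass


def label_proportion(
    sample_activity_bq, scaling, supplied_activity_bq: float, clamp: bool = True
):
    """Proportion P_r of the supplied 14C label present in a pool.

    ``scaling`` carries any dilution/subsample factor that scales the
    measured aliquot activity up to the whole pool. Values above 1 are
    physically impossible and are clamped to 1 with a warning.
    """
    if supplied_activity_bq <= 0:
        raise ValueError("supplied activity must be strictly positive")
    p_r = np.asarray(sample_activity_bq, dtype=float) * scaling / supplied_activity_bq
    if clamp and np.any(p_r > 1.0):
        warnings.warn(
            "label proportion exceeded 1; clamped (check dilution factors)",
            stacklevel=2,
        )
        p_r = np.minimum(p_r, 1.0)
    return p_r if p_r.ndim else float(p_r)


def carbon_in_pool(p_r, m_c: float):
    """Carbon mass (g) in a pool holding label proportion ``p_r``."""
    p = np.asarray(p_r, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("label proportion must lie in [0, 1]")
    out = p * m_c
    return out if out.ndim else float(out)


def peak_flux_time(curve: RespirationCurve) -> float:
    """Sampling time (h) of maximal below-ground 14C flux.

    Ties break to the earliest time; an all-zero curve yields NaN with a
    warning. Requires at least three sampling points.
    """
    if len(curve.times_h) < 3:
        raise ValueError("peak detection requires >= 3 sampling points")
    if np.all(curve.activities_bq == 0):
        warnings.warn("all-zero gas curve; peak time undefined", stacklevel=2)
        return float("nan")
    return float(curve.times_h[int(np.argmax(curve.activities_bq))])


def koh_trap_total(trap_records: pd.DataFrame) -> float:
    """Total respired activity (Bq) recovered in a core's KOH traps.

    Each 2-h interval contributes its background-subtracted aliquot
    activity scaled by the trap/aliquot volume ratio; intervals are summed
    over the incubation. An empty record set gives 0.
    """
    if len(trap_records) == 0:
        return 0.0
    bq = dpm_to_bq(trap_records["dpm"].to_numpy(), trap_records["background_dpm"].to_numpy())
    scale = (
        trap_records["total_volume_ml"].to_numpy()
        / trap_records["aliquot_volume_ml"].to_numpy()
    )
    return float(np.sum(bq * scale))


def pool_activities(campaign: Campaign) -> pd.DataFrame:
    """Per-pot whole-pool activities (Bq) for plant tissue, core and respiration.

    Plant-tissue digests are scaled by the digest dilution factor and the
    dry-mass/subsample-mass ratio (geometry from the tissue table); core
    digests represent the whole core contents and scale by their dilution
    factor only.
    """
    pots = campaign.labelled_pots()[["pot_id"]]
    scint = campaign.scint
    tissue = campaign.tissue.set_index("pot_id")

    digests = scint[scint["matrix"] == "tissue_digest"]
    out = pots.set_index("pot_id")
    out["a_plant_bq"] = np.nan
    out["a_core_bq"] = np.nan
    out["a_respired_bq"] = 0.0

    plant = digests[digests["compartment"] == "plant"]
    for _, row in plant.iterrows():
        pot = row["pot_id"]
        if pot not in tissue.index:
            warnings.warn(
                f"pot {pot}: plant 14C digest without tissue geometry; skipped",
                stacklevel=2,
            )
            continue
        geom = tissue.loc[pot]
        mass_scale = geom["dry_mass_g"] * 1e3 / geom["digest_subsample_mass_mg"]
        vol_scale = row["total_volume_ml"] / row["aliquot_volume_ml"]
        out.loc[pot, "a_plant_bq"] = (
            dpm_to_bq(row["dpm"], row["background_dpm"]) * vol_scale * mass_scale
        )

    core = digests[digests["compartment"] == "core"]
    for _, row in core.iterrows():
        vol_scale = row["total_volume_ml"] / row["aliquot_volume_ml"]
        out.loc[row["pot_id"], "a_core_bq"] = (
            dpm_to_bq(row["dpm"], row["background_dpm"]) * vol_scale
        )

    traps = scint[scint["matrix"] == "koh_trap"]
    for pot, grp in traps.groupby("pot_id"):
        out.loc[pot, "a_respired_bq"] = koh_trap_total(grp)
    return out.reset_index()


def total_carbon_fixed(
    campaign: Campaign,
    include_respired: bool = True,
    volume_interpretation: str = "mixing_ratio",
) -> pd.DataFrame:
    """Per-pot carbon budget (g) from the 14C records.

    Returns one row per labelled pot with the carbon recovered in the plant
    tissue (``c_plant_g``), the labelled core (``c_core_g``) and the KOH
    respiration traps (``c_respired_g``), plus ``total_c_fixed_g`` — the sum
    of plant, core and (by default) respired pools. The chamber residual is
    excluded: carbon that remained as chamber CO2 was never fixed. Pots
    whose plant digest is missing get NA totals with a warning upstream.
    """
    pots = campaign.labelled_pots()
    acts = pool_activities(campaign).set_index("pot_id")
    supplied = campaign.design.c14_supplied_activity_bq

    rows = []
    for _, pot in pots.iterrows():
        state = ChamberState.from_design(
            campaign.design, pot["co2_ppm"], volume_interpretation
        )
        m_c = chamber_carbon_mass(state)
        a = acts.loc[pot["pot_id"]]
        c_plant = (
            carbon_in_pool(label_proportion(a["a_plant_bq"], 1.0, supplied), m_c)
            if np.isfinite(a["a_plant_bq"])
            else np.nan
        )
        c_core = (
            carbon_in_pool(label_proportion(a["a_core_bq"], 1.0, supplied), m_c)
            if np.isfinite(a["a_core_bq"])
            else np.nan
        )
        c_resp = carbon_in_pool(label_proportion(a["a_respired_bq"], 1.0, supplied), m_c)
        total = c_plant + c_core + (c_resp if include_respired else 0.0)
        rows.append(
            {
                "pot_id": pot["pot_id"],
                "c_plant_g": c_plant,
                "c_core_g": c_core,
                "c_respired_g": c_resp,
                "total_c_fixed_g": total,
                "chamber_carbon_g": m_c,
            }
        )
    out = pd.DataFrame(rows)
    if out["total_c_fixed_g"].isna().any():
        missing = out.loc[out["total_c_fixed_g"].isna(), "pot_id"].tolist()
        warnings.warn(f"pots with incomplete 14C records (NA totals): {missing}", stacklevel=2)
    return out


def belowground_curve(campaign: Campaign, pot_id: str) -> RespirationCurve:
    """Below-ground gas-sampling curve for one pot (whole-sample Bq vs h)."""
    rows = campaign.scint
    rows = rows[(rows["matrix"] == "belowground_gas") & (rows["pot_id"] == pot_id)]
    rows = rows.sort_values("time_since_label_h")
    return RespirationCurve(
        rows["time_since_label_h"].to_numpy(dtype=float),
        dpm_to_bq(rows["dpm"].to_numpy(), rows["background_dpm"].to_numpy()),
    )
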