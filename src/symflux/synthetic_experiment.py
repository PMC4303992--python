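"""Forward simulation of a dual-isotope labelling campaign with known truth.

The generator emulates the physical experiment end to end: a 2 species x
2 CO2 factorial of pots, each labelled pot carrying one mesh-walled core
(static or rotated) injected with 33P-orthophosphate and 15NH4Cl, a 21 d
chase, then a sealed-chamber 14CO2 pulse. Every measured table the readers
consume (scintillation records, tissue digests, gas curves, KOH traps) is
emitted with expectations that invert *exactly* through the quantification
pipeline to the configured truth, so parameter-recovery and conservation
studies need no external data.

Noise model: Poisson counting noise on expected scintillation counts
(physical for radioactive decay; applied to counts accumulated over the
configured count time), Gaussian IRMS noise on atom % 15N, and an optional
mean-one lognormal between-pot biological variability on fixation,
allocation and nutrient delivery. A scalar diffusion leak routes a fraction
of each hyphal quantity into rotated-core pots (and additively into static
ones), so static-minus-rotated differencing recovers the hyphal transfer
itself.

All magnitudes of the canned scenario are synthetic choices for
testability; no simulator output represents measured field data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import (
    DPM_PER_BQ,
    N15_NATURAL_ABUNDANCE_ATOM_PCT,
    P_MOLAR_MASS,
)
from .experiment_model import Campaign, ExperimentDesign, validate_campaign
from .nutrient_tracers import decay_correction_factor
from .radiocarbon_flux import ChamberState, chamber_carbon_mass

__all__ = [
    "CellTruth",
    "TruthParams",
    "SimulationError",
    "simulate_campaign",
    "scenario_liverwort_co2",
]

#: KOH trap incubation: three 2-h intervals following the 17-h peak, with
#: a front-loaded split of the respired label across intervals.
_KOH_TIMES_H = (19.0, 21.0, 23.0)
_KOH_WEIGHTS = (0.5, 0.3, 0.2)

#: Gas sampling grids: headspace after 1 h then every 4 h; below-ground
#: after 1 h then every 2 h.
_HEADSPACE_TIMES_H = tuple(float(t) for t in range(1, 22, 4))
_BELOWGROUND_TIMES_H = tuple(float(t) for t in range(1, 24, 2))


class SimulationError(ValueError):
    """Raised for infeasible truth parameters."""


@dataclass(frozen=True)
class CellTruth:
    """Ground truth for one species x CO2 treatment cell."""

    total_fixation_g: float  # carbon fixed per pot during the pulse
    allocation_fraction: float  # of fixed C, routed to the core network
    respired_fraction: float  # of fixed C, respired below ground (KOH)
    p_delivery_ng: float  # 33P delivered to the plant via hyphae
    n_delivery_ng: float  # 15N delivered to the plant via hyphae
    diffusion_leak_fraction: float = 0.05  # reaches rotated cores
    peak_time_h: float = 17.0  # mode of the below-ground flux curve

    def validate(self) -> None:
        for name in ("allocation_fraction", "respired_fraction", "diffusion_leak_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.allocation_fraction * (1.0 + self.diffusion_leak_fraction) + self.respired_fraction > 1.0:
            raise SimulationError("allocation (with leak) plus respiration exceeds fixation")
        if self.total_fixation_g < 0 or self.p_delivery_ng < 0 or self.n_delivery_ng < 0:
            raise SimulationError("fixation and deliveries must be nonnegative")


@dataclass(frozen=True)
class TruthParams:
    """Full generative configuration of a simulated campaign."""

    cells: dict[tuple[str, float], CellTruth]
    counting_noise: str = "poisson"  # 'off' | 'poisson'
    irms_sd_atom_pct: float = 0.0005
    pot_cv: float = 0.15  # mean-one lognormal between-pot biological CV
    count_time_min: float = 5.0
    background_dpm_c14: float = 30.0
    controls_per_species: int = 2
    seed: int = 0

    def validate(self, design: ExperimentDesign) -> None:
        if self.counting_noise not in ("off", "poisson"):
            raise SimulationError(f"unknown counting_noise {self.counting_noise!r}")
        if self.irms_sd_atom_pct < 0 or self.pot_cv < 0:
            raise SimulationError("noise magnitudes must be nonnegative")
        for cell in design.cells():
            if cell not in self.cells:
                raise SimulationError(f"no truth configured for cell {cell}")
            self.cells[cell].validate()

    def noiseless(self) -> "TruthParams":
        """Copy with all stochastic measurement/biological noise disabled."""
        return replace(self, counting_noise="off", irms_sd_atom_pct=0.0, pot_cv=0.0)


def _gamma_pulse(times: np.ndarray, peak_h: float, shape: float = 4.0) -> np.ndarray:
    """Unimodal gamma-kinetics pulse with mode at ``peak_h``, max value 1."""
    t = np.asarray(times, dtype=float)
    return (t / peak_h) ** shape * np.exp(shape * (1.0 - t / peak_h))


def simulate_campaign(
    design: ExperimentDesign,
    truth: TruthParams,
    seed: int | None = None,
) -> tuple[Campaign, pd.DataFrame]:
    """Simulate one campaign; returns (validated campaign, per-pot truth record).

    All randomness flows from a single generator seeded by ``seed`` (default
    ``truth.seed``); two runs with the same seed produce identical tables.
    The truth record carries, per labelled pot, the realized pool split of
    the supplied 14C activity (tissue, core, respired, chamber residual) and
    the true delivered nutrient masses.
    """
    truth.validate(design)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    noisy_counts = truth.counting_noise == "poisson"

    def observe_dpm(expected: np.ndarray | float) -> np.ndarray | float:
        if not noisy_counts:
            return expected
        counts = rng.poisson(np.asarray(expected, dtype=float) * truth.count_time_min)
        return counts / truth.count_time_min

    a_sup = design.c14_supplied_activity_bq
    bg = truth.background_dpm_c14
    decay = decay_correction_factor(design.chase_duration_days)  # counts->label date

    pots, scint, tissue, truth_rows = [], [], [], []

    for species, co2 in design.cells():
        cell = truth.cells[(species, co2)]
        m_c = chamber_carbon_mass(ChamberState.from_design(design, co2))
        n = design.replicates_per_cell
        n_static = (n + 1) // 2
        for i in range(n):
            treatment = "static" if i < n_static else "rotated"
            pot_id = f"{species[:4]}_{co2:g}_{i + 1:02d}"
            pots.append(
                {
                    "pot_id": pot_id,
                    "species": species,
                    "co2_ppm": co2,
                    "core_treatment": treatment,
                    "labelled": True,
                }
            )

            # Between-pot biological variability (mean-one lognormal).
            if truth.pot_cv > 0:
                sigma = np.sqrt(np.log1p(truth.pot_cv**2))
                g_fix, g_alloc, g_p, g_n = np.exp(
                    rng.normal(-0.5 * sigma**2, sigma, size=4)
                )
            else:
                g_fix = g_alloc = g_p = g_n = 1.0

            fixed_g = cell.total_fixation_g * g_fix
            f_fix = fixed_g / m_c
            if f_fix >= 0.98:
                raise SimulationError(
                    f"pot {pot_id}: configured fixation {fixed_g:g} g approaches the "
                    f"chamber carbon mass {m_c:g} g"
                )
            alloc = cell.allocation_fraction * g_alloc
            leak = cell.diffusion_leak_fraction
            if alloc * (1.0 + leak) + cell.respired_fraction > 1.0:
                raise SimulationError(f"pot {pot_id}: realized pool fractions exceed 1")
            core_frac = alloc * (1.0 + leak) if treatment == "static" else alloc * leak
            resp_frac = cell.respired_fraction
            tissue_frac = 1.0 - core_frac - resp_frac

            a_tissue = a_sup * f_fix * tissue_frac
            a_core = a_sup * f_fix * core_frac
            a_resp = a_sup * f_fix * resp_frac
            a_resid = a_sup * (1.0 - f_fix)

            dry_mass_g = rng.uniform(0.2, 0.4)
            sub_mg = rng.uniform(10.0, 30.0)
            pct_n = rng.uniform(1.5, 2.5)
            mass_scale = sub_mg / (dry_mass_g * 1e3)
            vol_scale = 2.0 / 10.0  # 2 ml counted of a 10 ml digest

            # 14C: plant-tissue digest, whole-core digest, KOH traps.
            scint.append(
                {
                    "sample_id": f"{pot_id}_c14_plant",
                    "pot_id": pot_id,
                    "matrix": "tissue_digest",
                    "compartment": "plant",
                    "dpm": observe_dpm(a_tissue * mass_scale * vol_scale * DPM_PER_BQ + bg),
                    "background_dpm": bg,
                    "aliquot_volume_ml": 2.0,
                    "total_volume_ml": 10.0,
                    "time_since_label_h": np.nan,
                }
            )
            scint.append(
                {
                    "sample_id": f"{pot_id}_c14_core",
                    "pot_id": pot_id,
                    "matrix": "tissue_digest",
                    "compartment": "core",
                    "dpm": observe_dpm(a_core * vol_scale * DPM_PER_BQ + bg),
                    "background_dpm": bg,
                    "aliquot_volume_ml": 2.0,
                    "total_volume_ml": 10.0,
                    "time_since_label_h": np.nan,
                }
            )
            for t_h, w in zip(_KOH_TIMES_H, _KOH_WEIGHTS):
                scint.append(
                    {
                        "sample_id": f"{pot_id}_koh_{t_h:g}",
                        "pot_id": pot_id,
                        "matrix": "koh_trap",
                        "compartment": None,
                        "dpm": observe_dpm(a_resp * w * 0.5 * DPM_PER_BQ + bg),
                        "background_dpm": bg,
                        "aliquot_volume_ml": 1.0,
                        "total_volume_ml": 2.0,
                        "time_since_label_h": t_h,
                    }
                )

            # Diagnostic gas curves (1 ml samples). Below-ground kinetics are
            # a gamma pulse peaking at the cell's peak time; headspace decays
            # as label is fixed. Amplitudes are synthetic and small.
            bgt = np.array(_BELOWGROUND_TIMES_H)
            bg_curve = 1e-4 * a_sup * f_fix * _gamma_pulse(bgt, cell.peak_time_h)
            bg_dpm = observe_dpm(bg_curve * DPM_PER_BQ + bg)
            for t_h, d in zip(bgt, np.atleast_1d(bg_dpm)):
                scint.append(
                    {
                        "sample_id": f"{pot_id}_bg_{t_h:g}",
                        "pot_id": pot_id,
                        "matrix": "belowground_gas",
                        "compartment": None,
                        "dpm": d,
                        "background_dpm": bg,
                        "aliquot_volume_ml": 1.0,
                        "total_volume_ml": 1.0,
                        "time_since_label_h": t_h,
                    }
                )
            hst = np.array(_HEADSPACE_TIMES_H)
            hs_curve = a_sup * (1e-6 / design.chamber_volume_m3) * np.exp(-hst / 10.0)
            hs_dpm = observe_dpm(hs_curve * DPM_PER_BQ + bg)
            for t_h, d in zip(hst, np.atleast_1d(hs_dpm)):
                scint.append(
                    {
                        "sample_id": f"{pot_id}_hs_{t_h:g}",
                        "pot_id": pot_id,
                        "matrix": "headspace_gas",
                        "compartment": None,
                        "dpm": d,
                        "background_dpm": bg,
                        "aliquot_volume_ml": 1.0,
                        "total_volume_ml": 1.0,
                        "time_since_label_h": t_h,
                    }
                )

            # Nutrients delivered to the plant: hyphal transfer (+ leak) in
            # static pots, leak only in rotated pots.
            route = (1.0 + leak) if treatment == "static" else leak
            p_pot_ng = cell.p_delivery_ng * g_p * route
            n_pot_ng = cell.n_delivery_ng * g_n * route

            # 33P: mass -> activity at labelling date -> decayed counts on a
            # 2-of-10 ml aliquot of the subsample digest.
            aliquot_mass_mg = p_pot_ng * 1e-6 * mass_scale * vol_scale
            dpm_33p = (
                aliquot_mass_mg
                / P_MOLAR_MASS
                * design.p33_specific_activity_bq_per_mmol
                / decay
                * DPM_PER_BQ
            )
            # 15N: atom % excess over natural abundance across the pot's N pool.
            n_pool_g = pct_n / 100.0 * dry_mass_g
            atom_pct = N15_NATURAL_ABUNDANCE_ATOM_PCT + 100.0 * (n_pot_ng * 1e-9) / n_pool_g
            if truth.irms_sd_atom_pct > 0:
                atom_pct = max(atom_pct + rng.normal(0.0, truth.irms_sd_atom_pct), 0.0)

            tissue.append(
                {
                    "pot_id": pot_id,
                    "dry_mass_g": dry_mass_g,
                    "digest_subsample_mass_mg": sub_mg,
                    "digest_total_volume_ml": 10.0,
                    "counted_aliquot_volume_ml": 2.0,
                    "dpm_33p": observe_dpm(dpm_33p),
                    "atom_pct_15n": atom_pct,
                    "pct_n": pct_n,
                }
            )
            truth_rows.append(
                {
                    "pot_id": pot_id,
                    "species": species,
                    "co2_ppm": co2,
                    "core_treatment": treatment,
                    "chamber_carbon_g": m_c,
                    "fixed_c_g": fixed_g,
                    "a_tissue_bq": a_tissue,
                    "a_core_bq": a_core,
                    "a_respired_bq": a_resp,
                    "a_residual_bq": a_resid,
                    "p_delivered_ng": p_pot_ng,
                    "n_delivered_ng": n_pot_ng,
                    "peak_time_h": cell.peak_time_h,
                }
            )

    # Unlabelled IRMS background controls, one set per species.
    for species in design.species_labels:
        for i in range(truth.controls_per_species):
            pot_id = f"{species[:4]}_ctrl_{i + 1:02d}"
            pots.append(
                {
                    "pot_id": pot_id,
                    "species": species,
                    "co2_ppm": design.co2_levels_ppm[0],
                    "core_treatment": None,
                    "labelled": False,
                }
            )
            atom_pct = N15_NATURAL_ABUNDANCE_ATOM_PCT
            if truth.irms_sd_atom_pct > 0:
                atom_pct = max(atom_pct + rng.normal(0.0, truth.irms_sd_atom_pct), 0.0)
            tissue.append(
                {
                    "pot_id": pot_id,
                    "dry_mass_g": rng.uniform(0.2, 0.4),
                    "digest_subsample_mass_mg": rng.uniform(10.0, 30.0),
                    "digest_total_volume_ml": 10.0,
                    "counted_aliquot_volume_ml": 2.0,
                    "dpm_33p": observe_dpm(0.0),
                    "atom_pct_15n": atom_pct,
                    "pct_n": rng.uniform(1.5, 2.5),
                }
            )

    campaign = validate_campaign(
        design, pd.DataFrame(pots), pd.DataFrame(scint), pd.DataFrame(tissue)
    )
    return campaign, pd.DataFrame(truth_rows)


def scenario_liverwort_co2(
    noise: bool = True,
    replicates_per_cell: int = 10,
    seed: int = 0,
) -> tuple[ExperimentDesign, TruthParams]:
    """Canned two-liverwort scenario mirroring the headline response pattern.

    Constructed so that (a) absolute carbon transfer to the fungal network
    rises at 1500 ppm CO2 for both hosts, with the Treubia-like species also
    raising its *percentage* allocation while the Haplomitrium-like one
    keeps it flat, and (b) fungal nutrient delivery does not rise with CO2,
    so P-for-C and N-for-C exchange efficiencies do not increase at
    1500 ppm. All magnitudes are synthetic choices for testability.
    """
    design = ExperimentDesign(
        species_labels=("Haplomitrium", "Treubia"),
        co2_levels_ppm=(440.0, 1500.0),
        replicates_per_cell=replicates_per_cell,
        p33_specific_activity_bq_per_mmol=1.0e8,
    )
    cells = {
        ("Haplomitrium", 440.0): CellTruth(2.0e-4, 0.050, 0.15, 300.0, 450.0),
        ("Haplomitrium", 1500.0): CellTruth(5.5e-4, 0.055, 0.15, 300.0, 450.0),
        ("Treubia", 440.0): CellTruth(2.5e-4, 0.040, 0.15, 320.0, 500.0),
        ("Treubia", 1500.0): CellTruth(5.0e-4, 0.100, 0.15, 250.0, 480.0),
    }
    truth = TruthParams(cells=cells, seed=seed)
    if not noise:
        truth = truth.noiseless()
    return design, truth
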