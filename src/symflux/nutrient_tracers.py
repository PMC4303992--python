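"""Fungus-to-plant nutrient transfer: 33P from scintillation counts, 15N from IRMS.

33P follows the specific-activity route: background-subtracted counts are
converted to activity, optionally decay-corrected back to the labelling
date (half-life 25.38 d over the 21 d chase), divided by the source
specific activity to give mmol of traced phosphorus, and multiplied by the
molar mass of P and the digest dilution factor:

    M33P = (c_DPM / 60) / S_Act * M_wt * Df.

15N follows the atom-percent-excess method: enrichment above the
unlabelled-control background, times the tissue nitrogen pool:

    15N mass = (atom% - background)/100 * (%N)/100 * tissue mass.

Both are normalized to the digested subsample mass to give a tissue
concentration, then scaled by the pot's dry mass to a per-pot total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    DPM_PER_BQ,
    N15_NATURAL_ABUNDANCE_ATOM_PCT,
    P33_HALF_LIFE_DAYS,
    P_MOLAR_MASS,
)
from .experiment_model import Campaign, ExperimentDesign

__all__ = [
    "P33Context",
    "N15Context",
    "decay_correction_factor",
    "mass_33p",
    "tissue_concentration",
    "mass_15n",
    "n15_background",
    "nutrient_totals",
]


@dataclass(frozen=True)
class P33Context:
    """Conversion context for the 33P specific-activity route.

    ``dilution_factor`` defaults to the digest protocol's 10 ml digest /
    2 ml counted aliquot = 5. ``chase_elapsed_days`` is the time from
    labelling to counting used for decay correction (ignored when
    ``decay_correct`` is off).
    """

    specific_activity_bq_per_mmol: float
    dilution_factor: float = 5.0
    p_molar_mass_mg_per_mmol: float = P_MOLAR_MASS
    chase_elapsed_days: float = 0.0
    half_life_days: float = P33_HALF_LIFE_DAYS
    decay_correct: bool = True

    def __post_init__(self) -> None:
        if self.specific_activity_bq_per_mmol <= 0:
            raise ValueError("specific activity must be strictly positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")

    @classmethod
    def from_design(cls, design: ExperimentDesign, **overrides) -> "P33Context":
        kwargs = dict(
            specific_activity_bq_per_mmol=design.p33_specific_activity_bq_per_mmol,
            chase_elapsed_days=design.chase_duration_days,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass(frozen=True)
class N15Context:
    """Background enrichment for atom-percent-excess accounting."""

    background_atom_pct: float = N15_NATURAL_ABUNDANCE_ATOM_PCT

    def __post_init__(self) -> None:
        if not 0.0 < self.background_atom_pct < 1.0:
            raise ValueError("background atom % must lie in (0, 1) — natural abundance ~0.366")


def decay_correction_factor(elapsed_days: float, half_life_days: float = P33_HALF_LIFE_DAYS) -> float:
    """Factor that corrects an activity measured after ``elapsed_days`` back to t=0."""
    return 2.0 ** (elapsed_days / half_life_days)


def mass_33p(dpm, ctx: P33Context):
    """Mass of 33P-traced phosphorus (g) in the whole digest.

    ``dpm`` is the background-subtracted count rate of the counted aliquot.
    """
    activity = np.asarray(dpm, dtype=float) / DPM_PER_BQ
    if np.any(activity < 0):
        raise ValueError("DPM must be nonnegative (background-subtracted upstream)")
    if ctx.decay_correct:
        activity = activity * decay_correction_factor(ctx.chase_elapsed_days, ctx.half_life_days)
    mmol = activity / ctx.specific_activity_bq_per_mmol
    mass_mg = mmol * ctx.p_molar_mass_mg_per_mmol * ctx.dilution_factor
    out = mass_mg * 1e-3
    return out if out.ndim else float(out)


def tissue_concentration(mass_g, subsample_mass_g, dry_mass_g):
    """Normalize a digest mass to (concentration g/g, per-pot total g)."""
    sub = np.asarray(subsample_mass_g, dtype=float)
    if np.any(sub <= 0):
        raise ValueError("subsample mass must be strictly positive")
    conc = np.asarray(mass_g, dtype=float) / sub
    total = conc * np.asarray(dry_mass_g, dtype=float)
    if conc.ndim:
        return conc, total
    return float(conc), float(total)


def mass_15n(atom_pct, pct_n, ctx: N15Context, tissue_mass_g):
    """Tracer-derived 15N mass (g) in ``tissue_mass_g`` of dry tissue.

    Negative excess after background subtraction clamps to zero with a
    warning (measurement noise on unenriched tissue).
    """
    a = np.asarray(atom_pct, dtype=float)
    n = np.asarray(pct_n, dtype=float)
    if np.any(a < 0) or np.any(n < 0):
        raise ValueError("atom % and % N must be nonnegative")
    excess = a - ctx.background_atom_pct
    if np.any(excess < 0):
        warnings.warn("atom % below background; excess clamped to 0", stacklevel=2)
        excess = np.maximum(excess, 0.0)
    out = (excess / 100.0) * (n / 100.0) * np.asarray(tissue_mass_g, dtype=float)
    return out if out.ndim else float(out)


def n15_background(campaign: Campaign, species: str) -> float:
    """Mean atom % 15N of a species' unlabelled control pots.

    Falls back to the natural-abundance constant (0.3663 atom %) with a
    warning when no controls were supplied.
    """
    controls = campaign.control_pots()
    controls = controls[controls["species"] == species]
    rows = campaign.tissue[campaign.tissue["pot_id"].isin(controls["pot_id"])]
    if len(rows) == 0:
        warnings.warn(
            f"no unlabelled controls for {species!r}; using natural abundance "
            f"{N15_NATURAL_ABUNDANCE_ATOM_PCT} atom %",
            stacklevel=2,
        )
        return N15_NATURAL_ABUNDANCE_ATOM_PCT
    return float(rows["atom_pct_15n"].mean())


def nutrient_totals(
    campaign: Campaign,
    decay_correct_p33: bool = True,
    p33_dilution_override: float | None = None,
) -> pd.DataFrame:
    """Per-pot 33P and 15N tissue totals and concentrations.

    Returns one row per labelled pot: ``p33_mass_g`` / ``p33_conc_g_per_g``
    from the specific-activity route (dilution factor from each row's
    digest geometry unless overridden) and ``n15_mass_g`` /
    ``n15_conc_g_per_g`` from atom-percent excess with per-species control
    backgrounds.
    """
    design = campaign.design
    pots = campaign.labelled_pots()
    tissue = campaign.tissue.set_index("pot_id")
    backgrounds = {sp: n15_background(campaign, sp) for sp in design.species_labels}

    rows = []
    clamped: list[str] = []
    for _, pot in pots.iterrows():
        pid = pot["pot_id"]
        if pid not in tissue.index:
            rows.append(
                {
                    "pot_id": pid,
                    "p33_mass_g": np.nan,
                    "p33_conc_g_per_g": np.nan,
                    "n15_mass_g": np.nan,
                    "n15_conc_g_per_g": np.nan,
                }
            )
            continue
        t = tissue.loc[pid]
        df = (
            p33_dilution_override
            if p33_dilution_override is not None
            else t["digest_total_volume_ml"] / t["counted_aliquot_volume_ml"]
        )
        ctx = P33Context.from_design(
            design, dilution_factor=float(df), decay_correct=decay_correct_p33
        )
        digest_mass = mass_33p(t["dpm_33p"], ctx)
        sub_g = t["digest_subsample_mass_mg"] * 1e-3
        p_conc, p_total = tissue_concentration(digest_mass, sub_g, t["dry_mass_g"])
        n_ctx = N15Context(background_atom_pct=backgrounds[pot["species"]])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            n_total = mass_15n(t["atom_pct_15n"], t["pct_n"], n_ctx, t["dry_mass_g"])
        if caught:
            clamped.append(pid)
        rows.append(
            {
                "pot_id": pid,
                "p33_mass_g": p_total,
                "p33_conc_g_per_g": p_conc,
                "n15_mass_g": n_total,
                "n15_conc_g_per_g": n_total / t["dry_mass_g"],
            }
        )
    if clamped:
        warnings.warn(
            f"atom % below background (excess clamped to 0) in pots: {clamped}",
            stacklevel=2,
        )
    return pd.DataFrame(rows)
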