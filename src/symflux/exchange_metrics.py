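"""Static-minus-rotated differencing, allocation percentages, exchange efficiency.

The mesh-core rotation control isolates fungal transport from diffusion:
rotated cores receive only the diffusive leak, so the difference of
treatment-cell means (static minus rotated) estimates the hyphal transfer
itself. Exchange ('mycorrhizal') efficiency is the nutrient mass delivered
to the plant per unit carbon the plant allocated to the fungal network
(ng ng^-1), computed per treatment cell from the net means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TransferEstimate",
    "fungal_transfer",
    "percent_allocation",
    "exchange_efficiency",
    "summarize_exchange",
]


@dataclass(frozen=True)
class TransferEstimate:
    """Net fungal transfer for one treatment cell."""

    net: float
    se: float
    n_static: int
    n_rotated: int
    negative: bool  # net < 0: diffusion exceeded apparent transport

    def clamped(self) -> float:
        """Net floored at zero, for use as an efficiency denominator."""
        return max(self.net, 0.0)


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def fungal_transfer(static_values, rotated_values) -> TransferEstimate:
    """Net mean transfer: mean(static) - mean(rotated), SE by quadrature.

    Negative nets are reported as-is (flagged), since diffusion exceeding
    apparent transport is scientifically informative; they are clamped only
    when used as efficiency denominators.
    """
    s = np.asarray(static_values, dtype=float)
    r = np.asarray(rotated_values, dtype=float)
    s, r = s[np.isfinite(s)], r[np.isfinite(r)]
    if len(s) == 0 or len(r) == 0:
        raise ValueError("both static and rotated samples must be nonempty")
    net = float(np.mean(s) - np.mean(r))
    se = float(np.hypot(_sem(s), _sem(r)))
    return TransferEstimate(net, se, len(s), len(r), negative=net < 0)


def percent_allocation(c_to_fungus: float, total_fixed: float) -> float:
    """Percent of plant-fixed carbon allocated to the fungal network.

    Clamped to [0, 100] with a warning; a zero or missing total gives NaN.
    """
    if not np.isfinite(total_fixed) or total_fixed == 0:
        warnings.warn("total fixed carbon is zero or missing; allocation is NA", stacklevel=2)
        return float("nan")
    if total_fixed < 0:
        raise ValueError("total fixed carbon must be nonnegative")
    pct = 100.0 * c_to_fungus / total_fixed
    if pct < 0.0 or pct > 100.0:
        warnings.warn(f"allocation {pct:.3g}% outside [0, 100]; clamped", stacklevel=2)
        pct = min(max(pct, 0.0), 100.0)
    return pct


def exchange_efficiency(nutrient_total: float, c_to_fungus: float) -> float:
    """Nutrient gained per unit carbon allocated (same mass units, ng ng^-1).

    A nonpositive or missing carbon denominator gives NaN with a warning
    (cell-level degeneracy, not fatal).
    """
    if not np.isfinite(c_to_fungus) or c_to_fungus <= 0:
        warnings.warn("nonpositive carbon transfer; efficiency is NA", stacklevel=2)
        return float("nan")
    if nutrient_total < 0:
        warnings.warn("negative nutrient total; efficiency is NA", stacklevel=2)
        return float("nan")
    return nutrient_total / c_to_fungus


def summarize_exchange(flux_table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell exchange summary from a per-pot flux table.

    Expects the columns produced by :func:`symflux.pipeline.quantify_campaign`
    (species, co2_ppm, core_treatment, c_to_fungus_ng, total_c_fixed_g,
    p33_mass_ng, n15_mass_ng, ...). Returns a tidy frame with one row per
    species x CO2 x response carrying value, se and n, where the net
    responses come from static-minus-rotated differencing of cell means and
    the efficiencies are ratios of those nets.
    """
    responses = []
    for (species, co2), cell in flux_table.groupby(["species", "co2_ppm"], observed=True):
        stat = cell[cell["core_treatment"] == "static"]
        rot = cell[cell["core_treatment"] == "rotated"]
        if len(stat) == 0 or len(rot) == 0:
            raise ValueError(
                f"cell ({species}, {co2:g} ppm) lacks a static or rotated pot; "
                "differencing is undefined"
            )

        def add(name, value, se, n):
            responses.append(
                {
                    "species": species,
                    "co2_ppm": co2,
                    "response": name,
                    "value": value,
                    "se": se,
                    "n": n,
                }
            )

        nets = {}
        for col, name in [
            ("c_to_fungus_ng", "net_c_to_fungus_ng"),
            ("p33_mass_ng", "net_p33_ng"),
            ("n15_mass_ng", "net_n15_ng"),
            ("p33_conc_ng_per_g", "net_p33_conc_ng_per_g"),
            ("n15_conc_ng_per_g", "net_n15_conc_ng_per_g"),
        ]:
            est = fungal_transfer(stat[col], rot[col])
            nets[name] = est
            add(name, est.net, est.se, est.n_static + est.n_rotated)

        totals = cell["total_c_fixed_g"].dropna()
        add("total_c_fixed_g", float(totals.mean()), _sem(totals.to_numpy()), len(totals))

        net_c = nets["net_c_to_fungus_ng"]
        pct = percent_allocation(net_c.net * 1e-9, float(totals.mean()))
        add("pct_allocation", pct, float("nan"), len(cell))

        denom = net_c.clamped()
        for nut, name in [("net_p33_ng", "p_for_c_efficiency"), ("net_n15_ng", "n_for_c_efficiency")]:
            add(
                name,
                exchange_efficiency(max(nets[nut].net, 0.0), denom),
                float("nan"),
                len(cell),
            )
    return pd.DataFrame(responses)
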