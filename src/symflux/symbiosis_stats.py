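"""Factorial species x CO2 ANOVA and Tukey post hoc letter groupings.

The factorial analysis uses Type II sums of squares (each main effect
adjusted for the other, the interaction adjusted for both), which tolerate
the unbalanced replicate counts that arise when pots are lost, and reduce
to the textbook decomposition on balanced data. Post hoc comparisons use
the studentized range with the Tukey-Kramer correction for unequal group
sizes, summarized as a compact letter display (groups sharing a letter do
not differ at the family-wise alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

__all__ = [
    "AnovaTerm",
    "AnovaReport",
    "TukeyLetters",
    "two_way_anova",
    "tukey_letters",
    "anova_table",
]


@dataclass(frozen=True)
class AnovaTerm:
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass(frozen=True)
class AnovaReport:
    """F-ratios for species, CO2 and their interaction on one response."""

    response: str
    terms: dict[str, AnovaTerm]
    residual_df: int
    method: str = "type-II"
    degenerate: bool = False

    def as_row(self) -> dict:
        row: dict = {"response": self.response}
        for name, t in self.terms.items():
            row[f"F_{name}"] = t.F
            row[f"p_{name}"] = t.p
            row[f"df_{name}"] = f"{t.df_num}, {t.df_den}"
        return row


@dataclass(frozen=True)
class TukeyLetters:
    """Compact letter display: group label -> letter string."""

    letters: dict[str, str]
    alpha: float = 0.05
    degenerate: bool = False

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


_TERMS = {"C(species)": "species", "C(co2)": "co2", "C(species):C(co2)": "species_x_co2"}


def two_way_anova(values, species, co2, response_name: str = "response") -> AnovaReport:
    """Species x CO2 factorial ANOVA with Type II sums of squares.

    Accepts per-pot response values with parallel factor arrays; unbalanced
    and missing data are tolerated (NA rows dropped). A term whose factor
    has a single realized level is dropped with a warning; a response with
    zero residual variance is reported as degenerate with F=0, p=1.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "species": np.asarray(species, dtype=object),
            "co2": np.asarray(co2, dtype=object),
        }
    ).dropna()
    n_sp, n_co2 = df["species"].nunique(), df["co2"].nunique()
    if len(df) < 4 or n_sp < 1 or n_co2 < 1:
        raise ValueError("ANOVA requires at least two cells with two observations")

    rhs = []
    if n_sp > 1:
        rhs.append("C(species)")
    else:
        warnings.warn("species factor has one level; term dropped", stacklevel=2)
    if n_co2 > 1:
        rhs.append("C(co2)")
    else:
        warnings.warn("CO2 factor has one level; term dropped", stacklevel=2)
    if n_sp > 1 and n_co2 > 1:
        rhs.append("C(species):C(co2)")
    if not rhs:
        raise ValueError("no testable terms: both factors are constant")

    model = smf.ols("y ~ " + " + ".join(rhs), data=df).fit()
    resid_df = int(model.df_resid)
    total_ss = float(np.sum((df["y"] - df["y"].mean()) ** 2))
    # Scale-aware zero threshold: a constant response has total_ss ~ eps^2,
    # so fall back to the magnitude of the values themselves.
    tol = 1e-12 * max(total_ss, len(df) * float(np.mean(df["y"] ** 2)), 1e-300)
    degenerate = float(model.ssr) <= tol

    terms: dict[str, AnovaTerm] = {}
    if degenerate:
        # Zero residual variance: a term either explains nothing (F=0, p=1)
        # or explains an exact structural difference (F unbounded, p=0).
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sm.stats.anova_lm(model, typ=2)
        for t in rhs:
            ss = float(table.loc[t, "sum_sq"])
            df_num = int(table.loc[t, "df"])
            if ss <= tol:
                terms[_TERMS[t]] = AnovaTerm(0.0, df_num, resid_df, 1.0)
            else:
                terms[_TERMS[t]] = AnovaTerm(float("inf"), df_num, resid_df, 0.0)
        return AnovaReport(response_name, terms, resid_df, degenerate=True)

    table = sm.stats.anova_lm(model, typ=2)
    for t in rhs:
        row = table.loc[t]
        terms[_TERMS[t]] = AnovaTerm(
            F=float(row["F"]),
            df_num=int(row["df"]),
            df_den=resid_df,
            p=float(row["PR(>F)"]),
        )
    return AnovaReport(response_name, terms, resid_df)


def _compact_letter_display(groups: list[str], differs) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` must be ordered (by mean) for a canonical display;
    ``differs(a, b)`` returns True when the pair is significantly different.
    """
    # Each 'letter' is the set of groups it spans; start with one letter
    # covering everything, split it on each significant pair, then drop
    # letters absorbed by (subsets of) others.
    letters: list[set[str]] = [set(groups)]
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            if not differs(a, b):
                continue
            for l in [l for l in letters if a in l and b in l]:
                letters.remove(l)
                letters.extend([l - {a}, l - {b}])
            letters = [
                l
                for l in letters
                if l and not any(l < other for other in letters)
            ]
    # Deduplicate while keeping order by first (lowest-mean) member.
    uniq: list[set[str]] = []
    for l in letters:
        if l not in uniq:
            uniq.append(l)
    order = {g: k for k, g in enumerate(groups)}
    uniq.sort(key=lambda l: min(order[g] for g in l))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for idx, l in enumerate(uniq):
        for g in sorted(l, key=order.get):
            out[g] += alphabet[idx]
    return out


def tukey_letters(
    means: dict[str, float],
    n: dict[str, int],
    mse: float,
    df: int,
    alpha: float = 0.05,
) -> TukeyLetters:
    """Tukey(-Kramer) all-pairwise comparisons as a compact letter display.

    ``means``/``n`` map group labels to cell means and sizes; ``mse`` and
    ``df`` come from the ANOVA residuals. Two groups differ when their
    studentized range statistic exceeds the alpha-level critical value
    q(1-alpha; k, df), with the Kramer harmonic form for unequal n. A zero
    MSE is degenerate: groups with distinct means get distinct letters.
    """
    groups = sorted(means, key=lambda g: (means[g], g))
    if len(groups) < 2:
        raise ValueError("letter display requires >= 2 groups")
    if mse < 0:
        raise ValueError("MSE must be nonnegative")

    if mse == 0.0:
        differs = lambda a, b: means[a] != means[b]  # noqa: E731
        return TukeyLetters(_compact_letter_display(groups, differs), alpha, degenerate=True)

    q_crit = studentized_range.ppf(1.0 - alpha, len(groups), df)

    def differs(a: str, b: str) -> bool:
        se = np.sqrt(mse / 2.0 * (1.0 / n[a] + 1.0 / n[b]))
        return abs(means[a] - means[b]) > q_crit * se

    return TukeyLetters(_compact_letter_display(groups, differs), alpha)


def anova_table(
    flux_table: pd.DataFrame,
    responses: dict[str, str] | None = None,
    alpha: float = 0.05,
    pots: str = "static",
) -> tuple[pd.DataFrame, dict[str, AnovaReport], dict[str, TukeyLetters]]:
    """Per-response F-ratio table plus letter groupings over species x CO2 cells.

    ``responses`` maps column names in the per-pot flux table to display
    names; the default covers the standard report (total fungal carbon,
    percent allocation, tissue nutrient concentrations, efficiencies).
    ``pots`` selects the analysis population: ``'static'`` (default) uses
    only pots with intact hyphal connections — rotated pots measure the
    diffusion control, not the biological response — while ``'all'`` keeps
    every labelled pot. Returns the tidy table, the full AnovaReport per
    response and the Tukey-Kramer letters over the species x CO2 groups.
    """
    if pots == "static" and "core_treatment" in flux_table.columns:
        flux_table = flux_table[flux_table["core_treatment"] == "static"]
    elif pots not in ("static", "all"):
        raise ValueError("pots must be 'static' or 'all'")
    if responses is None:
        responses = {
            "c_to_fungus_ng": "total fungal carbon (ng)",
            "pct_allocation": "% plant-fixed carbon allocated to fungus",
            "p33_conc_ng_per_g": "[33P] in plant tissue (ng/g)",
            "n15_conc_ng_per_g": "[15N] in plant tissue (ng/g)",
            "p_for_c_efficiency": "P-for-C efficiency (ng/ng)",
            "n_for_c_efficiency": "N-for-C efficiency (ng/ng)",
        }
    reports: dict[str, AnovaReport] = {}
    letters: dict[str, TukeyLetters] = {}
    rows = []
    for col, name in responses.items():
        if col not in flux_table.columns:
            continue
        sub = flux_table.dropna(subset=[col])
        report = two_way_anova(sub[col], sub["species"], sub["co2_ppm"], response_name=name)
        reports[name] = report
        rows.append(report.as_row())

        cells = sub.groupby(["species", "co2_ppm"], observed=True)[col]
        means = {f"{s} @ {c:g} ppm": float(m) for (s, c), m in cells.mean().items()}
        sizes = {f"{s} @ {c:g} ppm": int(k) for (s, c), k in cells.size().items()}
        cell_dev = sub.groupby(["species", "co2_ppm"], observed=True)[col].transform("mean")
        resid = sub[col] - cell_dev
        df_resid = len(sub) - len(means)
        mse = float((resid**2).sum() / df_resid) if df_resid > 0 else 0.0
        if len(means) >= 2:
            letters[name] = tukey_letters(means, sizes, mse, max(df_resid, 1), alpha)
    return pd.DataFrame(rows), reports, letters
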