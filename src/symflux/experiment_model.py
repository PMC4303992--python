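"""Domain types, validation and file I/O for a dual-isotope labelling campaign.

A *campaign* is one run of the factorial pulse-chase experiment: a set of
pots (species x CO2 treatment, each labelled pot carrying one mesh-walled
soil core that is either left static or rotated daily), together with the
liquid-scintillation records, tissue digests and isotope-ratio
mass-spectrometry output collected at harvest.

All tabular data are held as pandas DataFrames with documented column
schemas; the dataclasses below describe one row of each table and carry the
row-level invariants. Masses are grams, activities becquerels, volumes of
digests and aliquots millilitres (pure ratios are all that is ever used of
them), and the chamber volume cubic metres.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "CampaignValidationError",
    "CampaignReferenceError",
    "ExperimentDesign",
    "PotRecord",
    "ScintillationRecord",
    "TissueMeasurement",
    "Campaign",
    "validate_campaign",
    "write_campaign",
    "read_campaign",
    "POT_COLUMNS",
    "SCINT_COLUMNS",
    "TISSUE_COLUMNS",
    "MATRICES",
    "CORE_TREATMENTS",
    "COMPARTMENTS",
]


class CampaignValidationError(ValueError):
    """Raised when campaign tables violate a schema invariant."""


class CampaignReferenceError(KeyError):
    """Raised when a record refers to a pot_id that does not exist."""


#: Scintillation sample matrices.
MATRICES = ("tissue_digest", "headspace_gas", "belowground_gas", "koh_trap")

#: Labelled-core handling: static preserves hyphal connections, rotated
#: severs them daily so only diffusion reaches the plant.
CORE_TREATMENTS = ("static", "rotated")

#: What a tissue_digest scintillation row was digested from: the plant
#: itself or the contents of the labelled mesh core.
COMPARTMENTS = ("plant", "core")

POT_COLUMNS = ["pot_id", "species", "co2_ppm", "core_treatment", "labelled"]
SCINT_COLUMNS = [
    "sample_id",
    "pot_id",
    "matrix",
    "compartment",
    "dpm",
    "background_dpm",
    "aliquot_volume_ml",
    "total_volume_ml",
    "time_since_label_h",
]
TISSUE_COLUMNS = [
    "pot_id",
    "dry_mass_g",
    "digest_subsample_mass_mg",
    "digest_total_volume_ml",
    "counted_aliquot_volume_ml",
    "dpm_33p",
    "atom_pct_15n",
    "pct_n",
]


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout, label doses and physical constants of one campaign.

    Field names carry explicit units. Defaults follow the labelling design
    this pipeline targets: a 0.5 MBq 33P-orthophosphate plus 15NH4Cl
    (1 mg ml^-1, 100 ul) injection into one mesh core per pot, a 21 d chase,
    then a 1.1 MBq 14CO2 pulse (source specific activity 2 GBq mmol^-1) in a
    sealed chamber whose CO2 holds 0.003 m^3 equivalent volume. The 33P
    source specific activity has no conventional default and must be given.
    """

    species_labels: tuple[str, ...]
    co2_levels_ppm: tuple[float, ...]
    replicates_per_cell: int
    p33_specific_activity_bq_per_mmol: float
    p33_supplied_activity_bq: float = 0.5e6
    c14_supplied_activity_bq: float = 1.1e6
    c14_specific_activity_bq_per_mmol: float = 2.0e9
    n15_solution_conc_mg_per_ml: float = 1.0
    n15_injection_volume_ml: float = 0.1
    chamber_volume_m3: float = 0.003
    temperature_k: float = 288.15
    pressure_kpa: float = 101.325
    chase_duration_days: float = 21.0

    def __post_init__(self) -> None:
        if len(self.species_labels) < 1:
            raise CampaignValidationError("at least one species label required")
        if len(set(self.species_labels)) != len(self.species_labels):
            raise CampaignValidationError("species labels must be unique")
        for ppm in self.co2_levels_ppm:
            if not 0.0 < ppm < 1e6:
                raise CampaignValidationError(f"CO2 level {ppm} ppm outside (0, 1e6)")
        if self.replicates_per_cell < 1:
            raise CampaignValidationError("replicates_per_cell must be >= 1")
        positive = [
            "p33_specific_activity_bq_per_mmol",
            "p33_supplied_activity_bq",
            "c14_supplied_activity_bq",
            "c14_specific_activity_bq_per_mmol",
            "n15_solution_conc_mg_per_ml",
            "n15_injection_volume_ml",
            "chamber_volume_m3",
            "temperature_k",
            "pressure_kpa",
            "chase_duration_days",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise CampaignValidationError(f"{name} must be strictly positive")

    def cells(self) -> list[tuple[str, float]]:
        """All (species, co2_ppm) treatment cells in declaration order."""
        return [(s, c) for s in self.species_labels for c in self.co2_levels_ppm]


@dataclass(frozen=True)
class PotRecord:
    """One experimental pot. Unlabelled pots serve as IRMS background controls."""

    pot_id: str
    species: str
    co2_ppm: float
    core_treatment: str | None  # static | rotated; None only for unlabelled pots
    labelled: bool = True

    def __post_init__(self) -> None:
        if self.labelled and self.core_treatment not in CORE_TREATMENTS:
            raise CampaignValidationError(
                f"pot {self.pot_id}: labelled pot requires core_treatment in {CORE_TREATMENTS}"
            )


@dataclass(frozen=True)
class ScintillationRecord:
    """One liquid-scintillation measurement (14C channel).

    ``matrix`` identifies the sample origin; for tissue digests
    ``compartment`` says whether plant tissue or core contents were digested.
    The dilution factor total_volume/aliquot_volume scales the counted
    aliquot back to the whole digest or trap.
    """

    sample_id: str
    pot_id: str
    matrix: str
    dpm: float
    background_dpm: float = 0.0
    aliquot_volume_ml: float = 1.0
    total_volume_ml: float = 1.0
    compartment: str | None = None
    time_since_label_h: float | None = None

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise CampaignValidationError(f"unknown matrix {self.matrix!r}")
        if self.matrix == "tissue_digest" and self.compartment not in COMPARTMENTS:
            raise CampaignValidationError(
                f"sample {self.sample_id}: tissue_digest rows need compartment in {COMPARTMENTS}"
            )
        if self.dpm < 0 or self.background_dpm < 0:
            raise CampaignValidationError(f"sample {self.sample_id}: negative DPM")
        if not 0 < self.aliquot_volume_ml <= self.total_volume_ml:
            raise CampaignValidationError(
                f"sample {self.sample_id}: aliquot must be positive and <= total volume"
            )

    @property
    def dilution_factor(self) -> float:
        return self.total_volume_ml / self.aliquot_volume_ml


@dataclass(frozen=True)
class TissueMeasurement:
    """Per-pot plant tissue analytics: digest geometry, 33P counts, IRMS output."""

    pot_id: str
    dry_mass_g: float
    digest_subsample_mass_mg: float
    dpm_33p: float
    atom_pct_15n: float
    pct_n: float
    digest_total_volume_ml: float = 10.0
    counted_aliquot_volume_ml: float = 2.0

    def __post_init__(self) -> None:
        if self.dry_mass_g <= 0:
            raise CampaignValidationError(f"pot {self.pot_id}: dry mass must be positive")
        if not 0 < self.digest_subsample_mass_mg <= self.dry_mass_g * 1e3:
            raise CampaignValidationError(
                f"pot {self.pot_id}: subsample mass must lie in (0, dry mass]"
            )
        if self.dpm_33p < 0:
            raise CampaignValidationError(f"pot {self.pot_id}: negative 33P DPM")
        if not 0 <= self.atom_pct_15n <= 100:
            raise CampaignValidationError(f"pot {self.pot_id}: atom % 15N outside [0, 100]")
        if not 0 <= self.pct_n <= 100:
            raise CampaignValidationError(f"pot {self.pot_id}: % N outside [0, 100]")
        if not 0 < self.counted_aliquot_volume_ml <= self.digest_total_volume_ml:
            raise CampaignValidationError(
                f"pot {self.pot_id}: counted aliquot must be <= digest volume"
            )


@dataclass
class Campaign:
    """A validated, cross-linked labelling campaign."""

    design: ExperimentDesign
    pots: pd.DataFrame
    scint: pd.DataFrame
    tissue: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def labelled_pots(self) -> pd.DataFrame:
        return self.pots[self.pots["labelled"]]

    def control_pots(self) -> pd.DataFrame:
        return self.pots[~self.pots["labelled"]]

    def cell_counts(self) -> pd.DataFrame:
        """Realized replicate counts per species x CO2 x core treatment."""
        lab = self.labelled_pots()
        return (
            lab.groupby(["species", "co2_ppm", "core_treatment"], observed=True)
            .size()
            .rename("n")
            .reset_index()
        )


def _as_frame(rows, columns: list[str], kind: str) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of dataclass records."""
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    if df.empty:
        return pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CampaignValidationError(f"{kind} table missing columns: {missing}")
    return df[columns]


def validate_campaign(design, pots, scint, tissue) -> Campaign:
    """Cross-link and validate the tables of one campaign.

    Parameters may be DataFrames following the documented schemas or
    iterables of the corresponding record dataclasses. Raises
    :class:`CampaignReferenceError` for dangling pot_ids and
    :class:`CampaignValidationError` for invariant violations; missing
    per-pot tissue rows are tolerated with a warning (downstream estimates
    for those pots become NA).
    """
    pots_df = _as_frame(pots, POT_COLUMNS, "pots")
    scint_df = _as_frame(scint, SCINT_COLUMNS, "scintillation")
    tissue_df = _as_frame(tissue, TISSUE_COLUMNS, "tissue")

    problems: list[str] = []
    if pots_df["pot_id"].duplicated().any():
        dupes = pots_df.loc[pots_df["pot_id"].duplicated(), "pot_id"].tolist()
        problems.append(f"duplicate pot_id values: {dupes}")

    labelled = pots_df[pots_df["labelled"].astype(bool)]
    bad_core = labelled[~labelled["core_treatment"].isin(CORE_TREATMENTS)]
    if len(bad_core):
        problems.append(
            "labelled pots without a static/rotated core assignment: "
            f"{bad_core['pot_id'].tolist()}"
        )

    known = set(pots_df["pot_id"])
    for name, df in (("scintillation", scint_df), ("tissue", tissue_df)):
        unknown = df[~df["pot_id"].isin(known)]
        if len(unknown):
            raise CampaignReferenceError(
                f"{name} rows reference unknown pot_id(s): "
                f"{sorted(set(unknown['pot_id']))} (rows {unknown.index.tolist()})"
            )

    if len(scint_df):
        bad = scint_df[(scint_df["dpm"] < 0) | (scint_df["background_dpm"] < 0)]
        if len(bad):
            problems.append(f"negative DPM in scintillation rows {bad.index.tolist()}")
        bad = scint_df[
            (scint_df["aliquot_volume_ml"] <= 0)
            | (scint_df["aliquot_volume_ml"] > scint_df["total_volume_ml"])
        ]
        if len(bad):
            problems.append(
                f"aliquot/total volume invariant violated in scintillation rows {bad.index.tolist()}"
            )
        td = scint_df[scint_df["matrix"] == "tissue_digest"]
        bad = td[~td["compartment"].isin(COMPARTMENTS)]
        if len(bad):
            problems.append(
                f"tissue_digest rows without plant/core compartment: {bad.index.tolist()}"
            )
        bad = scint_df[~scint_df["matrix"].isin(MATRICES)]
        if len(bad):
            problems.append(f"unknown matrix in scintillation rows {bad.index.tolist()}")

    if len(tissue_df):
        bad = tissue_df[
            (tissue_df["dry_mass_g"] <= 0)
            | (tissue_df["digest_subsample_mass_mg"] <= 0)
            | (tissue_df["digest_subsample_mass_mg"] > tissue_df["dry_mass_g"] * 1e3)
        ]
        if len(bad):
            problems.append(f"mass invariant violated in tissue rows {bad.index.tolist()}")
        bad = tissue_df[
            (tissue_df["dpm_33p"] < 0)
            | ~tissue_df["atom_pct_15n"].between(0, 100)
            | ~tissue_df["pct_n"].between(0, 100)
        ]
        if len(bad):
            problems.append(f"count/percent invariant violated in tissue rows {bad.index.tolist()}")
        if tissue_df["pot_id"].duplicated().any():
            problems.append("multiple tissue rows per pot")

    if problems:
        raise CampaignValidationError("; ".join(problems))

    warnings_list: list[str] = []
    no_tissue = set(labelled["pot_id"]) - set(tissue_df["pot_id"])
    if no_tissue:
        warnings_list.append(
            f"labelled pots without a tissue measurement (will be NA): {sorted(no_tissue)}"
        )
    return Campaign(design, pots_df, scint_df, tissue_df, warnings_list)


# ---------------------------------------------------------------------------
# File I/O: one YAML config (keys mirror ExperimentDesign, units in names)
# plus three CSV tables. Floats round-trip at full precision.

_CONFIG = "design.yaml"
_FILES = {"pots": "pots.csv", "scint": "scintillation.csv", "tissue": "tissue.csv"}


def write_campaign(campaign: Campaign, directory: str | Path) -> Path:
    """Write a campaign to ``directory`` as design.yaml + three CSV tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    design = dataclasses.asdict(campaign.design)
    design["species_labels"] = list(design["species_labels"])
    design["co2_levels_ppm"] = list(design["co2_levels_ppm"])
    (directory / _CONFIG).write_text(yaml.safe_dump(design, sort_keys=True))
    for attr, fname in _FILES.items():
        getattr(campaign, {"scint": "scint"}.get(attr, attr)).to_csv(
            directory / fname, index=False
        )
    return directory


def read_campaign(directory: str | Path) -> Campaign:
    """Read and re-validate a campaign written by :func:`write_campaign`."""
    directory = Path(directory)
    raw = yaml.safe_load((directory / _CONFIG).read_text())
    raw["species_labels"] = tuple(raw["species_labels"])
    raw["co2_levels_ppm"] = tuple(float(c) for c in raw["co2_levels_ppm"])
    design = ExperimentDesign(**raw)
    pots = pd.read_csv(directory / _FILES["pots"])
    scint = pd.read_csv(directory / _FILES["scint"])
    tissue = pd.read_csv(directory / _FILES["tissue"])
    # CSV round-trips None as NaN; normalize the optional text columns.
    for col in ("core_treatment",):
        pots[col] = pots[col].where(pots[col].notna(), None)
    if len(scint):
        scint["compartment"] = scint["compartment"].where(scint["compartment"].notna(), None)
    return validate_campaign(design, pots, scint, tissue)
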