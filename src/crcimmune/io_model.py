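"""Data model, readers/writers and configuration parsing.

The pipeline starts after image segmentation: its inputs are per-cell tables
(one row per segmented cell with marker intensities), per-core tissue areas,
a clinical table, and two configuration files (gating rules, positivity
thresholds).  All tabular exchange is CSV: UTF-8, comma-separated, ``.``
decimal separator, literal ``NA`` for missing values.

Cells from different antibody panels come from different tissue sections and
are therefore kept in independent tables; they are only ever joined at the
case level.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, ParseError, SchemaError

# ---------------------------------------------------------------------------
# Enumerations (plain strings; validated at the boundaries)
# ---------------------------------------------------------------------------

REGIONS = ("CT", "IM")            # central tumor / invasive margin
COMPARTMENTS = ("tumor", "stroma")
#: The four (region, compartment) localizations of the TMA design.
LOCALIZATIONS = tuple((r, c) for r in REGIONS for c in COMPARTMENTS)

NA_TOKEN = "NA"

# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelDefinition:
    """An antibody panel: ordered marker list plus subcellular localization.

    FoxP3 is a nuclear transcription factor; every other marker in the three
    panels is read out in the cytoplasmic/membrane compartment.
    """

    name: str
    markers: tuple[str, ...]
    localization: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        loc = dict(self.localization)
        for m in self.markers:
            loc.setdefault(m, "nuclear" if m == "FoxP3" else "cytoplasmic_membrane")
        object.__setattr__(self, "localization", loc)

    def canonical(self, name: str) -> str:
        """Case-insensitive marker lookup, canonicalized to panel spelling."""
        for m in self.markers:
            if m.lower() == name.lower():
                return m
        raise ConfigError(f"marker {name!r} is not part of panel {self.name!r}")


LYMPHOCYTE_PANEL = PanelDefinition(
    "lymphocyte", ("CD4", "CD8", "CD20", "FoxP3", "CD45RO", "panCK")
)
NK_MACROPHAGE_PANEL = PanelDefinition(
    "nk_macrophage", ("CD56", "NKp46", "CD3", "CD68", "CD163", "panCK")
)
DENDRITIC_PANEL = PanelDefinition(
    "dendritic", ("CD3", "CD1a", "CD208", "CD123", "CD68", "CD15", "panCK")
)

PANELS: dict[str, PanelDefinition] = {
    p.name: p for p in (LYMPHOCYTE_PANEL, NK_MACROPHAGE_PANEL, DENDRITIC_PANEL)
}


def get_panel(name: str) -> PanelDefinition:
    try:
        return PANELS[name]
    except KeyError:
        raise ConfigError(
            f"unknown panel {name!r}; expected one of {sorted(PANELS)}"
        ) from None


# ---------------------------------------------------------------------------
# Core record types
# ---------------------------------------------------------------------------


@dataclass
class CellRecord:
    """One segmented cell with spatial context and raw marker intensities."""

    cell_id: str
    case_id: str
    core_id: str
    region: str            # CT | IM
    compartment: str       # tumor | stroma
    x_um: float
    y_um: float
    intensities: dict[str, float]


@dataclass(frozen=True)
class ThresholdSet:
    """Per-panel marker positivity cutoffs (same arbitrary units as intensities)."""

    panel: str
    thresholds: Mapping[str, float]

    def __post_init__(self) -> None:
        pdef = get_panel(self.panel)
        canon = {pdef.canonical(m): float(v) for m, v in self.thresholds.items()}
        missing = [m for m in pdef.markers if m not in canon]
        if missing:
            raise ConfigError(
                f"panel {self.panel!r}: markers without a threshold: {missing}"
            )
        bad = {m: v for m, v in canon.items() if not (v > 0) or not math.isfinite(v)}
        if bad:
            raise ConfigError(f"thresholds must be positive and finite, got {bad}")
        object.__setattr__(self, "thresholds", canon)

    def __getitem__(self, marker: str) -> float:
        return self.thresholds[marker]


@dataclass
class RegionArea:
    """Analyzed tissue area (mm^2) of one (case, region, compartment, panel)."""

    case_id: str
    region: str
    compartment: str
    panel: str
    area_mm2: float


# ---------------------------------------------------------------------------
# Cell tables
# ---------------------------------------------------------------------------

_CELL_META_COLS = ("cell_id", "case_id", "core_id", "region", "compartment", "x_um", "y_um")


@dataclass
class CellTable:
    """A validated per-cell table for one panel.

    Backed by a :class:`pandas.DataFrame` with the metadata columns plus one
    numeric intensity column per panel marker (canonical spelling).  Row order
    of the source file is preserved.
    """

    panel: PanelDefinition
    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[CellRecord]:
        markers = list(self.panel.markers)
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield CellRecord(
                cell_id=d["cell_id"],
                case_id=d["case_id"],
                core_id=d["core_id"],
                region=d["region"],
                compartment=d["compartment"],
                x_um=d["x_um"],
                y_um=d["y_um"],
                intensities={m: d[m] for m in markers},
            )

    def intensity_matrix(self) -> pd.DataFrame:
        return self.df[list(self.panel.markers)]


def _match_columns(header: Iterable[str], panel: PanelDefinition) -> dict[str, str]:
    """Map file column names onto canonical names (case-insensitive markers)."""
    rename: dict[str, str] = {}
    lower_markers = {m.lower(): m for m in panel.markers}
    for col in header:
        key = col.strip()
        if key in _CELL_META_COLS:
            rename[col] = key
        elif key.lower() in lower_markers:
            rename[col] = lower_markers[key.lower()]
    return rename


def read_cell_table(
    path: str | Path,
    panel: PanelDefinition | str,
    *,
    coords_in_pixels: bool = False,
    pixels_per_um: float = 2.0,
) -> CellTable:
    """Read and validate a per-cell CSV for one panel.

    Marker columns are matched case-insensitively and canonicalized.  By
    default coordinates are taken as micrometres already; scanner-pixel
    coordinates can be converted with ``coords_in_pixels=True`` (the scan
    resolution is 2 pixels per µm).
    """
    if isinstance(panel, str):
        panel = get_panel(panel)
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.rename(columns=_match_columns(raw.columns, panel))

    missing = [c for c in (*_CELL_META_COLS, *panel.markers) if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    df = raw[list(_CELL_META_COLS) + list(panel.markers)].copy()
    bad_lines: list[str] = []

    for col in ("region", "compartment"):
        allowed = REGIONS if col == "region" else COMPARTMENTS
        bad = ~df[col].isin(allowed)
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
            bad_lines.append(
                f"column {col!r}: unknown token(s) {sorted(df.loc[bad, col].unique())}"
                f" at line(s) {lines[:10]}"
            )

    numeric_cols = ["x_um", "y_um", *panel.markers]
    for col in numeric_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals) | (vals < 0)
        if bad.any():
            lines = (df.index[bad] + 2).tolist()
            bad_lines.append(
                f"column {col!r}: non-numeric, non-finite or negative value(s)"
                f" at line(s) {lines[:10]}"
            )
        df[col] = vals.astype(float)

    if bad_lines:
        raise ParseError(f"{path}: " + "; ".join(bad_lines))
    if coords_in_pixels:
        df["x_um"] = df["x_um"] / pixels_per_um
        df["y_um"] = df["y_um"] / pixels_per_um
    return CellTable(panel=panel, df=df.reset_index(drop=True))


def write_cell_table(table: CellTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.6g")


# ---------------------------------------------------------------------------
# Area tables
# ---------------------------------------------------------------------------

_AREA_COLS = ("case_id", "region", "compartment", "panel", "area_mm2")


def read_area_table(path: str | Path) -> pd.DataFrame:
    """Read analyzed-area records; one row per (case, region, compartment, panel)."""
    path = Path(path)
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)
    missing = [c for c in _AREA_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = df[list(_AREA_COLS)].copy()
    if not df["region"].isin(REGIONS).all():
        raise ParseError(f"{path}: unknown region token in area table")
    if not df["compartment"].isin(COMPARTMENTS).all():
        raise ParseError(f"{path}: unknown compartment token in area table")
    df["area_mm2"] = pd.to_numeric(df["area_mm2"], errors="raise")
    if (df["area_mm2"].dropna() <= 0).any():
        raise ParseError(f"{path}: area_mm2 must be > 0")
    key = ["case_id", "region", "compartment", "panel"]
    if df.duplicated(key).any():
        dups = df.loc[df.duplicated(key), key].iloc[0].tolist()
        raise DataError(f"{path}: duplicate area record for {dups}")
    return df


def write_area_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.6g")


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

#: Ordered anatomical sites, proximal to distal.
TUMOR_LOCATIONS = (
    "caecum",
    "ascending_colon",
    "flexura_hepatica",
    "transverse_colon",
    "flexura_lienalis",
    "descending_colon",
    "sigmoid_colon",
    "rectum",
)
STAGES = ("I", "II", "III", "IV")
TREATMENT_GROUPS = ("naive", "RT_immediate", "RT_CRT_delayed")
MSI_STATUSES = ("MSS", "MSI-H", "unknown")

_CLINICAL_REQUIRED = (
    "case_id", "age_years", "sex", "tumor_location", "stage",
    "os_time_days", "os_event", "rfs_time_days", "rfs_event",
)
_CLINICAL_OPTIONAL = (
    "pT", "pN", "msi_status", "grade", "treatment_group",
    "surgery_type", "adjuvant_treatment",
)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-case clinical table."""
    path = Path(path)
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)
    missing = [c for c in _CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df["case_id"].duplicated().any():
        raise DataError(f"{path}: duplicate case_id")
    if not df["stage"].dropna().isin(STAGES).all():
        raise ParseError(f"{path}: unknown stage token")
    if not df["tumor_location"].dropna().isin(TUMOR_LOCATIONS).all():
        raise ParseError(f"{path}: unknown tumor_location token")
    if "treatment_group" in df.columns:
        if not df["treatment_group"].dropna().isin(TREATMENT_GROUPS).all():
            raise ParseError(f"{path}: unknown treatment_group token")
    for col in ("os_time_days", "rfs_time_days"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if (df[col].dropna() < 0).any():
            raise DataError(f"{path}: negative value in {col}")
    for col in ("os_event", "rfs_event"):
        df[col] = df[col].astype(float).astype("Int64")
        has_event = df[col] == 1
        tcol = col.replace("_event", "_time_days")
        if (has_event & ~np.isfinite(df[tcol].astype(float))).any():
            raise DataError(f"{path}: {col}=1 requires a finite {tcol}")
    both = df["rfs_time_days"].notna() & df["os_time_days"].notna()
    if (df.loc[both, "rfs_time_days"] > df.loc[both, "os_time_days"] + 1e-9).any():
        raise DataError(f"{path}: rfs_time_days exceeds os_time_days")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.6g")


# ---------------------------------------------------------------------------
# Density / score tables (long format; deterministic order, NA token)
# ---------------------------------------------------------------------------

_DENSITY_COLS = ("case_id", "subclass", "region", "compartment",
                 "n_cells", "area_mm2", "density")
_DENSITY_SORT = ["case_id", "subclass", "region", "compartment"]


def write_density_table(densities: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format density table, sorted deterministically.

    Missing areas/densities are written as the literal ``NA`` token so that a
    re-parse distinguishes missing from empty.  Values round-trip at 6
    significant digits.
    """
    try:
        df = densities[list(_DENSITY_COLS)].sort_values(_DENSITY_SORT, kind="mergesort")
        df.to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.6g")
    except OSError as exc:
        raise DataError(f"cannot write density table to {path}: {exc}") from exc


def read_density_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)
    missing = [c for c in _DENSITY_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in ("n_cells", "area_mm2", "density"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


_SCORE_COLS = ("case_id", "subclass", "CT_tumor", "CT_stroma",
               "IM_tumor", "IM_stroma", "score")


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    try:
        df = scores[list(_SCORE_COLS)].sort_values(
            ["case_id", "subclass"], kind="mergesort"
        )
        df.to_csv(path, index=False, na_rep=NA_TOKEN, float_format="%.6g")
    except OSError as exc:
        raise DataError(f"cannot write score table to {path}: {exc}") from exc


def read_score_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=False)
    missing = [c for c in _SCORE_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


# ---------------------------------------------------------------------------
# Configuration files (YAML, schema_version-ed)
# ---------------------------------------------------------------------------


def _load_yaml(path: str | Path) -> dict:
    path = Path(path)
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    if "schema_version" not in doc:
        raise ConfigError(f"{path}: missing schema_version")
    return doc


def read_thresholds(path: str | Path) -> dict[str, ThresholdSet]:
    """Read the per-panel positivity thresholds file."""
    doc = _load_yaml(path)
    panels = doc.get("panels")
    if not isinstance(panels, dict):
        raise ConfigError(f"{path}: expected a 'panels' mapping")
    return {name: ThresholdSet(panel=name, thresholds=vals)
            for name, vals in panels.items()}


def read_rules(path: str | Path):
    """Read a gating rules file into an ordered RuleSet (see :mod:`crcimmune.gating`)."""
    from .gating import GatingRule, RuleSet

    doc = _load_yaml(path)
    raw_rules = doc.get("rules")
    if not isinstance(raw_rules, list) or not raw_rules:
        raise ConfigError(f"{path}: expected a non-empty 'rules' list")
    rules = []
    seen: set[str] = set()
    for entry in raw_rules:
        name = entry.get("subclass")
        if name in seen:
            raise ConfigError(f"{path}: duplicate subclass name {name!r}")
        seen.add(name)
        panel = get_panel(entry.get("panel", ""))
        canon = lambda ms: tuple(panel.canonical(m) for m in (ms or []))
        rules.append(
            GatingRule(
                subclass=name,
                panel=panel.name,
                all_of=canon(entry.get("all_of")),
                any_of=canon(entry.get("any_of")),
                none_of=canon(entry.get("none_of")),
            )
        )
    return RuleSet(rules=tuple(rules))


def default_rules_path() -> Path:
    return Path(str(resources.files("crcimmune.data").joinpath("rules_default.yaml")))


def default_thresholds_path() -> Path:
    return Path(str(resources.files("crcimmune.data").joinpath("thresholds_default.yaml")))


def load_default_rules():
    return read_rules(default_rules_path())


def load_default_thresholds() -> dict[str, ThresholdSet]:
    return read_thresholds(default_thresholds_path())
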