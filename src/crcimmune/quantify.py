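"""Cell densities in the four-localization TMA design.

Each case contributes cores from the central tumor (CT) and the invasive
margin (IM); within each core, cells sit in the tumor or the stromal
compartment.  Infiltration is expressed as cells per mm^2 of analyzed tissue
area, per immune subclass, in each of the four (region, compartment)
localizations.

Zero versus missing: a localization with an area record but no cells of a
subclass is a true density of 0; a localization without an area record is
missing.  Cells recorded in a localization without an area record are a data
error — counts without a denominator are meaningless.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .gating import OTHER_LABEL, RuleSet
from .io_model import LOCALIZATIONS

#: Localizations with less analyzed tissue than this are treated as missing
#: (guards against near-zero-area blowups from fragmented cores).
DEFAULT_MIN_AREA_MM2 = 0.01


def compute_densities(
    phenotyped: pd.DataFrame,
    areas: pd.DataFrame,
    subclasses: list[str] | tuple[str, ...],
    panel: str,
    *,
    include_other: bool = False,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
) -> pd.DataFrame:
    """Compute cells/mm^2 per (case, subclass, region, compartment).

    Counts and areas from multiple cores of the same (case, region,
    compartment) are pooled (summed) before division.  Every localization
    with an area record yields an explicit row for every subclass, density 0
    when no cells of that subclass were seen.

    Parameters
    ----------
    phenotyped
        Gated cell table with ``case_id, region, compartment, subclass``.
    areas
        Area table with ``case_id, region, compartment, panel, area_mm2``.
    subclasses
        Subclass labels to quantify (the rule set's labels for this panel).
    panel
        Panel name; only area rows of this panel are used.
    """
    labels = list(subclasses)
    if include_other and OTHER_LABEL not in labels:
        labels.append(OTHER_LABEL)

    area_pool = (
        areas.loc[areas["panel"] == panel]
        .groupby(["case_id", "region", "compartment"], sort=True)["area_mm2"]
        .sum()
    )

    counts = (
        phenotyped.groupby(["case_id", "region", "compartment", "subclass"], sort=True)
        .size()
        .rename("n_cells")
    )

    # cells in a localization without an area record → error
    cell_locs = set(
        phenotyped.groupby(["case_id", "region", "compartment"], sort=True).groups
    )
    missing_area = sorted(cell_locs - set(area_pool.index))
    if missing_area:
        raise DataError(
            f"cells recorded in localization(s) without an area record "
            f"(panel {panel!r}): {missing_area[:5]}"
        )

    idx = pd.MultiIndex.from_tuples(
        [(c, r, k, s) for (c, r, k) in area_pool.index for s in labels],
        names=["case_id", "region", "compartment", "subclass"],
    )
    out = counts.reindex(idx, fill_value=0).reset_index()
    out = out.merge(
        area_pool.rename("area_mm2").reset_index(),
        on=["case_id", "region", "compartment"],
        how="left",
    )
    usable = out["area_mm2"] >= min_area_mm2
    out["density"] = np.where(usable, out["n_cells"] / out["area_mm2"], np.nan)
    out.loc[~usable, "area_mm2"] = np.nan
    return out[["case_id", "subclass", "region", "compartment",
                "n_cells", "area_mm2", "density"]]


def density_matrix(densities: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long density table to cases x (subclass, region, compartment).

    Localizations a case does not cover are NaN (missing, not zero).
    """
    wide = densities.pivot_table(
        index="case_id",
        columns=["subclass", "region", "compartment"],
        values="density",
        dropna=False,
    )
    wide.columns.names = ["subclass", "region", "compartment"]
    return wide.sort_index(axis=1)


def cube_root_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise cube root, the display transform for skewed densities.

    Missing values stay missing; negative densities are a domain error.
    """
    vals = matrix.to_numpy(dtype=float)
    if np.nanmin(vals, initial=0.0) < 0:
        raise ValueError("densities must be non-negative")
    return matrix ** (1.0 / 3.0)


def localization_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-(subclass, localization) median/mean/n plus per-subclass negativity.

    ``fraction_zero`` is the share of cases whose density is exactly 0 in
    *every* covered localization of the subclass (a "negative" case, the way
    NK/NKT negativity is reported); it is repeated on each of the subclass's
    rows.  Columns where every case is missing are NaN throughout.
    """
    rows = []
    for subclass in matrix.columns.get_level_values("subclass").unique():
        block = matrix[subclass]
        covered = block.notna().any(axis=1)
        negative = (block.eq(0) | block.isna()).all(axis=1) & covered
        frac_zero = negative.sum() / covered.sum() if covered.any() else np.nan
        for col in block.columns:
            vals = block[col].dropna()
            rows.append({
                "subclass": subclass,
                "region": col[0],
                "compartment": col[1],
                "n": len(vals),
                "median": vals.median() if len(vals) else np.nan,
                "mean": vals.mean() if len(vals) else np.nan,
                "fraction_zero": frac_zero,
            })
    return pd.DataFrame(rows)


def pooled_case_density(densities: pd.DataFrame) -> pd.DataFrame:
    """One overall density per (case, subclass): total cells / total area.

    Pools the four localizations; used for cohort-level summaries and the
    treatment-group comparisons.
    """
    g = densities.dropna(subset=["area_mm2"]).groupby(
        ["case_id", "subclass"], sort=True
    )
    out = g.agg(n_cells=("n_cells", "sum"), area_mm2=("area_mm2", "sum")).reset_index()
    out["density"] = out["n_cells"] / out["area_mm2"]
    return out


def check_counts_conservation(
    phenotyped: pd.DataFrame, densities: pd.DataFrame
) -> bool:
    """True iff per-localization subclass counts in *densities* sum to the
    gated cell count for that localization (requires include_other=True)."""
    lhs = (
        densities.groupby(["case_id", "region", "compartment"])["n_cells"].sum()
    )
    rhs = (
        phenotyped.groupby(["case_id", "region", "compartment"]).size()
    )
    lhs_aligned, rhs_aligned = lhs.align(rhs, fill_value=0)
    return bool((lhs_aligned == rhs_aligned).all())
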