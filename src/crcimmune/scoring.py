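"""The per-subclass immune score (0-4).

For each immune subclass, a case's density in each of the four localizations
is dichotomized against the cohort median of that localization: 1 if strictly
above the median, 0 otherwise.  The sum over the four localizations gives an
integer score between 0 and 4.  Strict ``>`` matters for zero-inflated
subclasses (NK, NKT): when the cohort median is 0, the majority-negative
cases must score "low", which a ``>=`` rule would invert.

Scores are complete-case: a case missing any of the four localizations gets
a missing score for that subclass.  Medians are by default computed on the
analysis subset being scored; a frozen median table can be supplied instead,
e.g. to score treated rectal cases against the therapy-naive reference.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import LOCALIZATIONS

DEFAULT_MIN_CASES = 2


def compute_medians(
    density_matrix: pd.DataFrame, *, min_cases: int = DEFAULT_MIN_CASES
) -> pd.Series:
    """Cohort median density per (subclass, region, compartment) column.

    Standard sample median (mean of the middle two for even n), over
    non-missing cases only.  Columns with fewer than *min_cases* non-missing
    values are flagged NaN, which propagates to a missing score component.
    """
    med = density_matrix.median(axis=0, skipna=True)
    n = density_matrix.notna().sum(axis=0)
    med[n < min_cases] = np.nan
    return med


def dichotomize(density: float, median: float) -> float:
    """1 if density is strictly above the median, 0 otherwise; NaN propagates."""
    if np.isnan(density) or np.isnan(median):
        return np.nan
    return 1.0 if density > median else 0.0


def immune_score(components: dict[tuple[str, str], float]) -> float:
    """Sum the four 0/1 localization components; missing if any is missing."""
    vals = [components[loc] for loc in LOCALIZATIONS]
    if any(np.isnan(v) for v in vals):
        return np.nan
    return float(sum(vals))


def score_components(
    density_matrix: pd.DataFrame, medians: pd.Series | None = None
) -> pd.DataFrame:
    """Per-localization 0/1 components for every case and subclass."""
    if medians is None:
        medians = compute_medians(density_matrix)
    medians = medians.reindex(density_matrix.columns)
    comp = density_matrix.gt(medians, axis=1).astype(float)
    comp[density_matrix.isna() | medians.isna()] = np.nan
    return comp


def score_matrix(
    density_matrix: pd.DataFrame, medians: pd.Series | None = None
) -> pd.DataFrame:
    """Cases x subclasses integer score matrix (NaN where incomplete).

    Each subclass must contribute its four localization columns; a case with
    any missing component has a missing score for that subclass.
    """
    comp = score_components(density_matrix, medians)
    scores = {}
    for subclass in comp.columns.get_level_values("subclass").unique():
        block = comp[subclass]
        # all four localizations must be present and non-missing
        full = block.reindex(columns=pd.MultiIndex.from_tuples(LOCALIZATIONS))
        scores[subclass] = full.sum(axis=1, min_count=len(LOCALIZATIONS))
    out = pd.DataFrame(scores, index=comp.index)
    out.columns.name = "subclass"
    return out


def complete_cases(scores: pd.DataFrame) -> pd.DataFrame:
    """Rows with a non-missing score for every subclass (the clustering set)."""
    return scores.dropna(axis=0, how="any")


def scores_long(scores: pd.DataFrame, comp: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format score table matching the on-disk schema."""
    rows = []
    for case_id, row in scores.iterrows():
        for subclass, score in row.items():
            rec = {"case_id": case_id, "subclass": subclass, "score": score}
            for r, c in LOCALIZATIONS:
                key = f"{r}_{c}"
                if comp is not None and (subclass, r, c) in comp.columns:
                    rec[key] = comp[(subclass, r, c)].loc[case_id]
                else:
                    rec[key] = np.nan
            rows.append(rec)
    return pd.DataFrame(rows)
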