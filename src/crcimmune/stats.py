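"""Statistical layer: correlation, clustering, group comparisons, survival.

Conventions used throughout (documented once):

* Spearman correlation with midrank ties, pairwise-complete observations.
* Hierarchical clustering with the Ward minimum-variance criterion on
  Euclidean distances (the "ward.D2"-equivalent formulation), on the raw
  0-4 score matrix without standardization — scores already share a scale.
* Mann-Whitney U: exact enumeration for small tie-free samples, otherwise
  normal approximation with tie and continuity corrections.
* Wilcoxon signed-rank with the Pratt zero-handling: zeros are ranked, then
  dropped from the statistic; asymptotic normal p with zero/tie-adjusted
  variance.
* Benjamini-Hochberg step-up q-values; one family per reported analysis
  (the 15 subclass tests of a panel), not a global family.
* Pearson Chi-square without continuity correction.
* Cox proportional hazards by partial likelihood with the Efron tie
  correction (day-resolution data produce heavy ties); Wald 95% CI and p.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss
from lifelines import CoxPHFitter, exceptions
from lifelines.exceptions import ConvergenceError
from statsmodels.stats.multitest import multipletests

from .errors import DataError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    rho: pd.DataFrame       # symmetric, unit diagonal; NaN where undefined
    p: pd.DataFrame
    significant: pd.DataFrame  # p < alpha, off-diagonal

    @property
    def columns(self) -> pd.Index:
        return self.rho.columns


def spearman_matrix(
    scores: pd.DataFrame, *, alpha: float = 0.05, min_cases: int = 3
) -> CorrelationMatrix:
    """Spearman correlation between every pair of score columns.

    Pairwise-complete: each pair uses the cases where both columns are
    observed.  Constant columns have undefined correlation (NaN, flagged
    non-significant).
    """
    cols = scores.columns
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        rho[i, i], pval[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            pair = scores.iloc[:, [i, j]].dropna()
            if len(pair) < min_cases:
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() < 2 or y.nunique() < 2:
                continue  # constant column: undefined
            r, p = ss.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pval, index=cols, columns=cols)
    sig = (p_df < alpha) & ~np.eye(k, dtype=bool)
    return CorrelationMatrix(rho=rho_df, p=p_df, significant=sig)


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    linkage: np.ndarray        # scipy linkage matrix (merge order + heights)
    labels: pd.Series          # cluster label per case at the requested cut
    k: int

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


def ward_cluster(scores: pd.DataFrame, k: int) -> ClusterResult:
    """Agglomerative Ward clustering of the complete-case score matrix.

    Merge heights are non-decreasing (Ward is reducible), and cutting the
    tree at *k* clusters labels every case.
    """
    X = scores.dropna(axis=0, how="any")
    n = len(X)
    if k < 1 or k > n:
        raise ValueError(f"k={k} outside [1, n={n}]")
    Z = sch.linkage(X.to_numpy(dtype=float), method="ward")
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(linkage=Z, labels=pd.Series(labels, index=X.index), k=k)


def silhouette(scores: pd.DataFrame, labels: pd.Series) -> float:
    """Mean silhouette width of a labeling of the complete-case set."""
    from sklearn.metrics import silhouette_score

    X = scores.loc[labels.index].to_numpy(dtype=float)
    return float(silhouette_score(X, labels.to_numpy()))


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 8


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    ``mode='auto'`` uses exact enumeration when both samples have at most
    8 observations and there are no ties, otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    if mode == "auto":
        tie_free = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
        mode = "exact" if (x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N
                           and tie_free) else "asymptotic"
    res = ss.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if mode == "exact" else "asymptotic",
        use_continuity=(mode != "exact"),
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_pratt(diffs) -> tuple[float, float]:
    """Wilcoxon signed-rank test with Pratt zero handling; returns (W, p).

    Zero differences participate in the ranking and are then dropped from
    the statistic; p is the asymptotic two-sided normal approximation with
    the zero/tie-adjusted variance.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0 or np.all(d == 0):
        raise DataError("signed-rank test undefined: no nonzero differences")
    res = ss.wilcoxon(d, zero_method="pratt", correction=False,
                      alternative="two-sided", method="approx")
    # report the positive-rank sum (W+) under the Pratt ranking; scipy's
    # two-sided statistic is min(W+, W-), which loses the direction
    ranks = ss.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def chi_square(table) -> tuple[float, float, int]:
    """Pearson Chi-square test of independence (no continuity correction)."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DataError("contingency table has a zero marginal")
    stat, p, dof, _ = ss.chi2_contingency(t, correction=False)
    return float(stat), float(p), int(dof)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class HazardEstimate:
    term: str
    endpoint: str              # OS | RFS
    model: str                 # univariable | multivariable
    hr: float
    ci_low: float
    ci_high: float
    p: float
    q: float = np.nan
    n: int = 0
    n_events: int = 0
    covariates: tuple[str, ...] = ()
    converged: bool = True
    note: str = ""


def build_endpoints(clinical: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Extract (time, event) for one endpoint from the clinical table.

    OS is time from surgery to death from any cause.  RFS is the composite
    of recurrence/progression and death from any cause, whichever comes
    first; the clinical table already carries the composite rfs columns, and
    their consistency (rfs <= os) is validated at read time.
    """
    if endpoint == "OS":
        out = clinical[["case_id", "os_time_days", "os_event"]].rename(
            columns={"os_time_days": "time", "os_event": "event"}
        )
    elif endpoint == "RFS":
        out = clinical[["case_id", "rfs_time_days", "rfs_event"]].rename(
            columns={"rfs_time_days": "time", "rfs_event": "event"}
        )
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    out = out.dropna(subset=["time", "event"])
    if (out["time"] < 0).any():
        raise DataError("negative survival time")
    out = out.copy()
    out["event"] = out["event"].astype(int)
    return out.set_index("case_id")


def compose_endpoint(
    surgery_to_recurrence: pd.Series | None,
    surgery_to_death: pd.Series,
    followup: pd.Series,
) -> pd.DataFrame:
    """Build a composite recurrence-free endpoint from raw event times.

    Each input is the (possibly NaN = never observed) number of days from
    surgery; the endpoint time is the earliest of recurrence and death, with
    censoring at last follow-up when neither occurred.
    """
    death = surgery_to_death.to_numpy(dtype=float)
    rec = (surgery_to_recurrence.to_numpy(dtype=float)
           if surgery_to_recurrence is not None
           else np.full_like(death, np.nan))
    cens = followup.to_numpy(dtype=float)
    first = np.fmin(rec, death)
    event = np.isfinite(first) & (first <= cens)
    time = np.where(event, first, cens)
    return pd.DataFrame(
        {"time": time, "event": event.astype(int)}, index=surgery_to_death.index
    )


def cox_fit(
    df: pd.DataFrame,
    *,
    duration_col: str = "time",
    event_col: str = "event",
    covariates: list[str] | None = None,
    term: str | None = None,
    endpoint: str = "OS",
    model: str = "univariable",
) -> list[HazardEstimate]:
    """Fit a Cox proportional-hazards model (Efron ties, Wald inference).

    Returns one :class:`HazardEstimate` per covariate.  Non-convergence
    (typically monotone likelihood from perfect separation) is flagged on
    the estimate rather than raised.
    """
    covariates = covariates or [
        c for c in df.columns if c not in (duration_col, event_col)
    ]
    data = df[[duration_col, event_col, *covariates]].dropna()
    n_events = int(data[event_col].sum())
    if n_events == 0:
        raise DataError("no events: Cox model undefined")
    constant = [c for c in covariates if data[c].nunique() <= 1]
    if constant:
        # a constant covariate carries no hazard information: HR 1 by convention
        return [
            HazardEstimate(term=c, endpoint=endpoint, model=model, hr=1.0,
                           ci_low=1.0, ci_high=1.0, p=1.0, n=len(data),
                           n_events=n_events, covariates=tuple(covariates),
                           note="constant covariate")
            for c in covariates
        ]
    cph = CoxPHFitter()
    try:
        import warnings

        with warnings.catch_warnings():
            # small-subgroup batch fits routinely warn about near-separation;
            # hard failures are still raised as ConvergenceError below
            warnings.simplefilter("ignore", category=exceptions.StatisticalWarning)
            warnings.simplefilter("ignore", category=exceptions.ConvergenceWarning)
            cph.fit(data, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        return [
            HazardEstimate(term=c, endpoint=endpoint, model=model,
                           hr=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
                           n=len(data), n_events=n_events,
                           covariates=tuple(covariates), converged=False,
                           note=f"non-convergence (monotone likelihood?): {exc}")
            for c in covariates
        ]
    summ = cph.summary
    out = []
    report_terms = [term] if term else covariates
    for c in report_terms:
        row = summ.loc[c]
        out.append(HazardEstimate(
            term=c, endpoint=endpoint, model=model,
            hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            p=float(row["p"]),
            n=len(data), n_events=n_events,
            covariates=tuple(covariates),
        ))
    return out


def hazards_to_frame(estimates: list[HazardEstimate]) -> pd.DataFrame:
    df = pd.DataFrame([e.__dict__ for e in estimates])
    return df.drop(columns=["covariates"], errors="ignore")


def cox_per_subclass(
    scores: pd.DataFrame,
    endpoints: pd.DataFrame,
    *,
    covariate_df: pd.DataFrame | None = None,
    coding: str = "continuous",
    endpoint: str = "OS",
) -> pd.DataFrame:
    """One Cox model per subclass score, BH-adjusted across the family.

    The score enters as a continuous 0-4 covariate by default, or
    median-dichotomized (``coding='dichotomized'``).  When *covariate_df* is
    given the models are multivariable, adjusted for those columns.
    """
    model = "univariable" if covariate_df is None else "multivariable"
    estimates: list[HazardEstimate] = []
    for subclass in scores.columns:
        s = scores[subclass].rename("score")
        if coding == "dichotomized":
            med = s.median(skipna=True)
            s = (s > med).astype(float).where(s.notna())
        df = endpoints.join(s, how="inner")
        if covariate_df is not None:
            df = df.join(covariate_df, how="inner")
        df = df.dropna()
        if df.empty or df["event"].sum() == 0:
            log.warning("subclass %s: no usable cases/events; model skipped", subclass)
            continue
        ests = cox_fit(df, term="score", endpoint=endpoint, model=model)
        e = ests[0]
        e.term = subclass
        estimates.append(e)
    out = hazards_to_frame(estimates)
    if len(out):
        fitted = out["p"].notna()
        q = np.full(len(out), np.nan)
        if fitted.any():
            q[fitted.to_numpy()] = bh_adjust(out.loc[fitted, "p"])
        out["q"] = q
    return out


# ---------------------------------------------------------------------------
# Composite analysis recipes
# ---------------------------------------------------------------------------


@dataclass
class CohortData:
    """Everything the composite analyses need, joined on case_id."""

    clinical: pd.DataFrame           # validated clinical table
    scores: pd.DataFrame             # cases x subclasses (wide)
    case_densities: pd.DataFrame | None = None  # pooled per (case, subclass)
    cluster_labels: pd.Series | None = None


@dataclass
class ReportBundle:
    enrichment: pd.DataFrame | None = None          # (a)
    os_univariable: pd.DataFrame | None = None      # (b)
    rfs_univariable: pd.DataFrame | None = None     # (c)
    rfs_multivariable: pd.DataFrame | None = None   # (c)
    stage4_os: pd.DataFrame | None = None           # (d)
    rectal_comparisons: pd.DataFrame | None = None  # (e)
    skipped: list[str] = field(default_factory=list)


_ENRICHMENT_COVARIATES = ("stage", "sex", "msi_status", "side")
_MULTI_COVARIATES = ("pT", "pN", "grade_num", "age_years",
                     "surgery_acute", "adjuvant_treatment")

RIGHT_SIDED = ("caecum", "ascending_colon", "flexura_hepatica", "transverse_colon")


def _prepare_covariates(clinical: pd.DataFrame) -> pd.DataFrame:
    cov = clinical.set_index("case_id").copy()
    cov["side"] = np.where(
        cov["tumor_location"].isin(RIGHT_SIDED), "right",
        np.where(cov["tumor_location"] == "rectum", "rectum", "left"),
    )
    if "grade" in cov.columns:
        cov["grade_num"] = pd.Categorical(
            cov["grade"], categories=["high", "moderate", "low"], ordered=True
        ).codes.astype(float)
    if "surgery_type" in cov.columns:
        cov["surgery_acute"] = (cov["surgery_type"] == "acute").astype(float)
    if "adjuvant_treatment" in cov.columns:
        cov["adjuvant_treatment"] = cov["adjuvant_treatment"].astype(float)
    return cov


def analysis_recipes(cohort: CohortData, *, coding: str = "continuous") -> ReportBundle:
    """Run the study's composite analysis set on a scored, clustered cohort.

    (a) cluster-by-covariate Chi-square enrichment; (b) univariable OS Cox in
    therapy-naive cases; (c) univariable and multivariable RFS Cox in stage
    I-III colon cancer, adjusted for pT, pN, differentiation, age, surgery
    type and adjuvant treatment; (d) stage-IV OS Cox; (e) rectal three-group
    density comparisons.  Analyses whose inputs are absent are skipped with a
    log entry.
    """
    bundle = ReportBundle()
    clin = cohort.clinical
    cov = _prepare_covariates(clin)
    naive_ids = clin.loc[
        clin.get("treatment_group", pd.Series("naive", index=clin.index)) == "naive",
        "case_id",
    ]

    # (a) cluster enrichment
    if cohort.cluster_labels is not None:
        rows = []
        for covariate in _ENRICHMENT_COVARIATES:
            if covariate not in cov.columns:
                continue
            joined = pd.DataFrame({
                "cluster": cohort.cluster_labels,
                "value": cov[covariate].reindex(cohort.cluster_labels.index),
            }).dropna()
            table = pd.crosstab(joined["cluster"], joined["value"])
            if table.shape[0] < 2 or table.shape[1] < 2:
                continue
            try:
                stat, p, dof = chi_square(table.to_numpy())
            except DataError:
                continue
            rows.append({"covariate": covariate, "statistic": stat,
                         "p": p, "df": dof})
        if rows:
            df = pd.DataFrame(rows)
            df["q"] = bh_adjust(df["p"])
            bundle.enrichment = df
    else:
        bundle.skipped.append("enrichment: no cluster labels")
        log.info("enrichment skipped: no cluster labels")

    # (b) univariable OS, therapy-naive
    naive_clin = clin[clin["case_id"].isin(naive_ids)]
    if len(naive_clin):
        ep = build_endpoints(naive_clin, "OS")
        bundle.os_univariable = cox_per_subclass(
            cohort.scores, ep, coding=coding, endpoint="OS"
        )
    else:
        bundle.skipped.append("os_univariable: no therapy-naive cases")
        log.info("os_univariable skipped: no therapy-naive cases")

    # (c) RFS in stage I-III colon
    colon13 = clin[
        clin["stage"].isin(["I", "II", "III"])
        & (clin["tumor_location"] != "rectum")
        & clin["case_id"].isin(naive_ids)
    ]
    if len(colon13):
        ep = build_endpoints(colon13, "RFS")
        bundle.rfs_univariable = cox_per_subclass(
            cohort.scores, ep, coding=coding, endpoint="RFS"
        )
        multi = [c for c in _MULTI_COVARIATES if c in cov.columns]
        missing = [c for c in _MULTI_COVARIATES if c not in cov.columns]
        if missing:
            bundle.skipped.append(f"rfs_multivariable: missing covariates {missing}")
            log.info("rfs_multivariable skipped: missing covariates %s", missing)
        else:
            bundle.rfs_multivariable = cox_per_subclass(
                cohort.scores, ep,
                covariate_df=cov[multi].apply(pd.to_numeric, errors="coerce"),
                coding=coding, endpoint="RFS",
            )
    else:
        bundle.skipped.append("rfs: no stage I-III colon cases")
        log.info("rfs recipes skipped: no stage I-III colon cases")

    # (d) stage IV OS
    stage4 = clin[(clin["stage"] == "IV") & clin["case_id"].isin(naive_ids)]
    if len(stage4) and build_endpoints(stage4, "OS")["event"].sum() > 0:
        ep = build_endpoints(stage4, "OS")
        bundle.stage4_os = cox_per_subclass(
            cohort.scores, ep, coding=coding, endpoint="OS"
        )
    else:
        bundle.skipped.append("stage4_os: no stage-IV cases (or no events)")
        log.info("stage4_os skipped: no stage-IV cases or no events")

    # (e) rectal treatment-group comparisons
    if cohort.case_densities is not None and "treatment_group" in clin.columns:
        rectal = clin[clin["tumor_location"] == "rectum"]
        groups = rectal.groupby("treatment_group")["case_id"].apply(list)
        if {"naive", "RT_immediate", "RT_CRT_delayed"} <= set(groups.index):
            bundle.rectal_comparisons = treatment_group_comparisons(
                cohort.case_densities, groups
            )
        else:
            bundle.skipped.append("rectal_comparisons: not all three groups present")
            log.info("rectal_comparisons skipped: not all three groups present")
    return bundle


def treatment_group_comparisons(
    case_densities: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Per-subclass density comparisons between treatment groups.

    For each subclass, compares naive vs RT-with-immediate-surgery and naive
    vs delayed-surgery pooled densities (Mann-Whitney, two-sided), each family
    BH-adjusted across subclasses, with the direction of the median effect.
    """
    wide = case_densities.pivot_table(
        index="case_id", columns="subclass", values="density"
    )
    rows = []
    for contrast, other in (("naive_vs_RT_immediate", "RT_immediate"),
                            ("naive_vs_delayed", "RT_CRT_delayed")):
        for subclass in wide.columns:
            a = wide.loc[wide.index.intersection(groups["naive"]), subclass].dropna()
            b = wide.loc[wide.index.intersection(groups[other]), subclass].dropna()
            if len(a) == 0 or len(b) == 0:
                continue
            u, p = mann_whitney(a, b)
            rows.append({
                "contrast": contrast, "subclass": subclass,
                "statistic": u, "p": p,
                "direction": float(np.sign(a.median() - b.median())),
                "n_naive": len(a), "n_other": len(b),
            })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = np.nan
        for contrast in out["contrast"].unique():
            m = out["contrast"] == contrast
            out.loc[m, "q"] = bh_adjust(out.loc[m, "p"])
    return out


def compartment_comparisons(density_matrix: pd.DataFrame) -> pd.DataFrame:
    """Case-wise stroma-vs-tumor comparison per subclass.

    Pools the two regions per compartment (mean of CT and IM densities),
    tests the paired difference with the Pratt signed-rank test, BH-adjusts
    across subclasses, and reports the sign of the median paired difference
    (positive = stroma-enriched).
    """
    rows = []
    for subclass in density_matrix.columns.get_level_values("subclass").unique():
        block = density_matrix[subclass]
        stroma = block.xs("stroma", level="compartment", axis=1).mean(axis=1)
        tumor = block.xs("tumor", level="compartment", axis=1).mean(axis=1)
        d = (stroma - tumor).dropna()
        if len(d) == 0 or np.all(d == 0):
            continue
        w, p = wilcoxon_pratt(d.to_numpy())
        rows.append({
            "subclass": subclass, "statistic": w, "p": p,
            "direction": float(np.sign(d.median())),
            "n": len(d),
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"])
    return out
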