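"""Synthetic cohort generator.

Emits everything the analysis pipeline consumes — per-panel cell tables,
analyzed-area records, a clinical table — together with the ground truth
behind them, so every downstream operation can be tested against known
answers.

The statistical structure emulated:

* two cohort archetypes, immune "inflamed" and immune "desert", mixed at a
  configurable fraction (default 145/373 of cases inflamed), separated by a
  log-scale shift of the T-lineage densities;
* lognormal per-case expected densities, correlated across T-cell subclasses
  through a shared latent "immune activation" factor;
* stromal enrichment of most subclasses with tumor-compartment enrichment of
  CD8 single-positive and myeloid cells;
* strong zero-inflation of NK and NKT abundances (defaults: 77% and 81% of
  cases fully negative);
* Poisson cell counts given expected density x analyzed area, cells placed
  uniformly within their compartment;
* marker intensities drawn on either side of the true thresholds so that,
  at zero label noise, gating recovers every cell's true subclass exactly;
* exponential proportional-hazards survival driven by true CD8 (protective,
  default HR 0.64) and M2 (adverse, default HR 1.50) high/low indicators;
* optional three-group rectal treatment design with radiation-induced
  depletion and post-delay repopulation.

Every public entry point takes an explicit integer seed and is fully
deterministic given (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .gating import OTHER_LABEL, RuleSet
from .io_model import (
    CellTable,
    LOCALIZATIONS,
    PANELS,
    REGIONS,
    ThresholdSet,
    load_default_rules,
    write_area_table,
    write_cell_table,
    write_clinical_table,
)

# ---------------------------------------------------------------------------
# Per-subclass density parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubclassParams:
    """Density model for one immune subclass.

    ``log_median`` is the log expected density (cells/mm^2) of a desert-
    archetype case in the CT stroma; ``tumor_ratio`` multiplies the density
    in the tumor compartment (<1 = stroma-enriched); ``ct_shift`` is the log
    excess in the central tumor vs the invasive margin; ``inflamed_shift``
    is the log shift of inflamed-archetype cases; ``latent_loading`` couples
    the subclass to the shared immune-activation factor; ``zero_inflation``
    is the probability that a case is entirely negative for the subclass.
    """

    panel: str
    log_median: float
    sigma: float = 1.0
    tumor_ratio: float = 0.35
    ct_shift: float = 0.0
    inflamed_shift: float = 0.0
    latent_loading: float = 0.0
    zero_inflation: float = 0.0


def _default_subclass_params() -> dict[str, SubclassParams]:
    ln = np.log
    return {
        # lymphocyte panel: T-lineage classes share the latent factor and the
        # archetype shift; CD8 single positives are tumor-enriched.
        "CD4_sp":     SubclassParams("lymphocyte", ln(200), 1.0, 0.35, 0.2, 3.0, 0.3),
        "CD8_sp":     SubclassParams("lymphocyte", ln(314), 1.0, 1.8, 0.2, 3.0, 0.3),
        "CD4_Treg":   SubclassParams("lymphocyte", ln(60), 1.0, 0.35, 0.2, 2.6, 0.3),
        "CD8_Treg":   SubclassParams("lymphocyte", ln(80), 1.0, 0.35, 0.2, 2.6, 0.3),
        "CD4_CD45RO": SubclassParams("lymphocyte", ln(150), 1.0, 0.35, 0.2, 3.0, 0.3),
        "CD8_CD45RO": SubclassParams("lymphocyte", ln(150), 1.0, 0.35, 0.2, 3.0, 0.3),
        "B_cell":     SubclassParams("lymphocyte", ln(100), 1.0, 0.25, 0.0, 2.0, 0.3),
        # NK/macrophage panel: NK and NKT are rare and strongly zero-inflated.
        "NK":  SubclassParams("nk_macrophage", ln(15), 0.8, 0.5, 0.0, 0.0, 0.0, 0.77),
        "NKT": SubclassParams("nk_macrophage", ln(10), 0.8, 0.5, 0.0, 0.0, 0.0, 0.81),
        "M1":  SubclassParams("nk_macrophage", ln(431), 0.8, 0.5, 0.0, 0.4, 0.3),
        "M2":  SubclassParams("nk_macrophage", ln(150), 0.8, 0.5, 0.0, -0.4, -0.2),
        # dendritic panel: myeloid cells are tumor-enriched.
        "iDC": SubclassParams("dendritic", ln(30), 0.8, 0.5),
        "mDC": SubclassParams("dendritic", ln(20), 0.8, 0.5, 0.0, -0.2),
        "pDC": SubclassParams("dendritic", ln(12), 0.8, 0.5, 0.0, -0.2),
        "myeloid": SubclassParams("dendritic", ln(100), 0.8, 1.8, 0.0, -0.3),
    }


#: Subclasses whose infiltration stays stable under neoadjuvant treatment.
TREATMENT_STABLE_SUBCLASSES = ("CD4_sp", "CD8_sp", "B_cell")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_cases: int = 373
    inflamed_fraction: float = 145 / 373
    subclass_params: Mapping[str, SubclassParams] = field(
        default_factory=_default_subclass_params
    )
    #: within-case log jitter between the four localizations
    localization_sigma: float = 0.25
    #: expected densities are capped here (cells/mm^2)
    density_cap: float = 12_000.0
    #: epithelial ("other") cell density in tumor / stroma compartments
    epithelial_density: tuple[float, float] = (800.0, 50.0)
    # analyzed areas: lognormal(log(area_mm2_median * area_scale), area_sigma)
    area_mm2_median: float = 0.25
    area_sigma: float = 0.25
    area_scale: float = 1.0
    # marker intensities: log offset and half-normal spread on either side of
    # the (true) threshold
    threshold_truth: float = 1.0
    intensity_margin: float = 0.15
    intensity_sigma: float = 0.7
    extra_positive_prob: float = 0.25
    epithelial_positive_prob: float = 0.15
    label_noise: float = 0.0
    # survival
    baseline_hazard: float = np.log(2) / 1500.0   # per day
    hr_cd8: float = 0.64
    hr_m2: float = 1.50
    recurrence_hazard_mult: float = 1.3
    censor_low_days: float = 180.0
    censor_high_days: float = 3600.0
    # rectal treatment design
    n_per_group: int = 26
    depletion_factor: float = 0.3
    recovery_factor: float = 1.0
    m1_persistent_depletion: bool = True
    m1_delayed_factor: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ConfigError("n_cases must be >= 0")
        if not 0 <= self.inflamed_fraction <= 1:
            raise ConfigError("inflamed_fraction must be in [0, 1]")
        for name, p in self.subclass_params.items():
            if p.panel not in PANELS:
                raise ConfigError(f"subclass {name!r}: unknown panel {p.panel!r}")
            if not 0 <= p.zero_inflation <= 1:
                raise ConfigError(f"subclass {name!r}: zero_inflation outside [0, 1]")
            if p.tumor_ratio <= 0 or p.sigma < 0:
                raise ConfigError(f"subclass {name!r}: infeasible density parameters")
        if self.depletion_factor <= 0 or self.recovery_factor <= 0:
            raise ConfigError("treatment factors must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if not (0 < self.hr_cd8 and 0 < self.hr_m2):
            raise ConfigError("hazard ratios must be > 0")


@dataclass
class GroundTruth:
    """What the generator actually did, keyed consistently with the tables."""

    case_truth: pd.DataFrame          # case_id, archetype, latent, cd8_high, m2_high
    expected_densities: pd.DataFrame  # case_id, subclass, region, compartment, density
    cell_truth: dict[str, pd.DataFrame]  # panel -> (cell_id, true_subclass)
    config: GeneratorConfig


@dataclass
class SimulatedCohort:
    cells: dict[str, CellTable]       # panel -> cell table
    areas: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Internals
# ---------------------------------------------------------------------------


def _draw_expected_densities(
    cfg: GeneratorConfig, rng: np.random.Generator,
    archetype: np.ndarray, latent: np.ndarray,
    group_factor: np.ndarray | None = None,
    group_factors_by_subclass: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-case expected density for every subclass and localization."""
    n = len(archetype)
    rows = []
    for subclass, p in cfg.subclass_params.items():
        eps = rng.normal(0.0, p.sigma, size=n)
        negative = rng.random(n) < p.zero_inflation
        for region in REGIONS:
            for compartment in ("tumor", "stroma"):
                jitter = rng.normal(0.0, cfg.localization_sigma, size=n)
                log_lam = (
                    p.log_median
                    + p.inflamed_shift * archetype
                    + p.latent_loading * latent
                    + eps
                    + jitter
                    + (np.log(p.tumor_ratio) if compartment == "tumor" else 0.0)
                    + (p.ct_shift if region == "CT" else 0.0)
                )
                lam = np.minimum(np.exp(log_lam), cfg.density_cap)
                lam[negative] = 0.0
                if group_factors_by_subclass and subclass in group_factors_by_subclass:
                    lam = lam * group_factors_by_subclass[subclass]
                elif group_factor is not None:
                    lam = lam * group_factor
                rows.append(pd.DataFrame({
                    "case_id": _case_ids(n),
                    "subclass": subclass,
                    "region": region,
                    "compartment": compartment,
                    "density": lam,
                }))
    return pd.concat(rows, ignore_index=True)


def _case_ids(n: int) -> np.ndarray:
    return np.array([f"case_{i:04d}" for i in range(n)], dtype=object)


def _draw_areas(cfg: GeneratorConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    rows = []
    mu = np.log(cfg.area_mm2_median * cfg.area_scale)
    for panel in PANELS:
        for region in REGIONS:
            for compartment in ("tumor", "stroma"):
                area = np.exp(rng.normal(mu, cfg.area_sigma, size=n))
                area = np.maximum(area, 0.02 * cfg.area_scale)
                rows.append(pd.DataFrame({
                    "case_id": _case_ids(n),
                    "region": region,
                    "compartment": compartment,
                    "panel": panel,
                    "area_mm2": area,
                }))
    return pd.concat(rows, ignore_index=True)


def _rule_for(rules: RuleSet, subclass: str):
    for r in rules.rules:
        if r.subclass == subclass:
            return r
    raise ConfigError(f"generator subclass {subclass!r} has no gating rule")


def _synthesize_panel_cells(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    panel_name: str,
    expected: pd.DataFrame,
    areas: pd.DataFrame,
    rules: RuleSet,
) -> tuple[CellTable, pd.DataFrame]:
    """Draw cells for one panel: counts, positions, calls, intensities."""
    panel = PANELS[panel_name]
    markers = list(panel.markers)
    n_mark = len(markers)
    panel_subclasses = [s for s, p in cfg.subclass_params.items()
                        if p.panel == panel_name]

    if cfg.n_cases == 0:
        df = pd.DataFrame(columns=[
            "cell_id", "case_id", "core_id", "region", "compartment",
            "x_um", "y_um", *markers,
        ])
        truth = pd.DataFrame(columns=["cell_id", "case_id", "true_subclass"])
        return CellTable(panel=panel, df=df), truth

    area_lookup = areas[areas["panel"] == panel_name].set_index(
        ["case_id", "region", "compartment"]
    )["area_mm2"]
    exp_lookup = expected.set_index(
        ["subclass", "region", "compartment"]
    ).sort_index()

    case_ids = _case_ids(cfg.n_cases)
    meta_case, meta_region, meta_comp, meta_sub = [], [], [], []
    for subclass in [*panel_subclasses, OTHER_LABEL]:
        for region, compartment in LOCALIZATIONS:
            if subclass == OTHER_LABEL:
                dens_t, dens_s = cfg.epithelial_density
                lam_density = np.full(
                    cfg.n_cases, dens_t if compartment == "tumor" else dens_s
                )
            else:
                block = exp_lookup.loc[(subclass, region, compartment)]
                lam_density = block.set_index("case_id")["density"].reindex(
                    case_ids
                ).to_numpy()
            area = area_lookup.loc[
                [(c, region, compartment) for c in case_ids]
            ].to_numpy()
            counts = rng.poisson(lam_density * area)
            meta_case.append(np.repeat(case_ids, counts))
            meta_region.append(np.repeat(region, counts.sum()))
            meta_comp.append(np.repeat(compartment, counts.sum()))
            meta_sub.append(np.repeat(subclass, counts.sum()))

    case_arr = np.concatenate(meta_case)
    region_arr = np.concatenate(meta_region)
    comp_arr = np.concatenate(meta_comp)
    sub_arr = np.concatenate(meta_sub)
    n_cells = len(case_arr)

    x = rng.uniform(0.0, 1000.0, size=n_cells)
    y = rng.uniform(0.0, 1000.0, size=n_cells)

    # --- true marker call vectors -------------------------------------
    calls = np.zeros((n_cells, n_mark), dtype=bool)
    midx = {m: i for i, m in enumerate(markers)}
    for subclass in panel_subclasses:
        sel = np.flatnonzero(sub_arr == subclass)
        if not len(sel):
            continue
        rule = _rule_for(rules, subclass)
        for m in rule.all_of:
            calls[sel, midx[m]] = True
        if rule.any_of:
            pick = rng.integers(0, len(rule.any_of), size=len(sel))
            for j, m in enumerate(rule.any_of):
                chosen = sel[pick == j]
                calls[chosen, midx[m]] = True
                extra = sel[(pick != j)
                            & (rng.random(len(sel)) < cfg.extra_positive_prob)]
                calls[extra, midx[m]] = True
    other_sel = np.flatnonzero(sub_arr == OTHER_LABEL)
    if len(other_sel):
        calls[other_sel, midx["panCK"]] = True
        for m in markers:
            if m == "panCK":
                continue
            on = other_sel[rng.random(len(other_sel)) < cfg.epithelial_positive_prob]
            calls[on, midx[m]] = True

    # --- label noise: flip one random marker call per affected cell ---
    if cfg.label_noise > 0:
        noisy = np.flatnonzero(rng.random(n_cells) < cfg.label_noise)
        flip = rng.integers(0, n_mark, size=len(noisy))
        calls[noisy, flip] = ~calls[noisy, flip]

    # --- intensities strictly on the right side of the true threshold -
    margin = cfg.intensity_margin + np.abs(
        rng.normal(0.0, cfg.intensity_sigma, size=(n_cells, n_mark))
    )
    log_int = np.where(calls, margin, -margin)
    intensities = cfg.threshold_truth * np.exp(log_int)

    order = np.argsort(case_arr, kind="stable")
    df = pd.DataFrame({
        "cell_id": "",
        "case_id": case_arr[order],
        "core_id": "",
        "region": region_arr[order],
        "compartment": comp_arr[order],
        "x_um": x[order],
        "y_um": y[order],
    })
    df["cell_id"] = [f"{panel_name}_{i:07d}" for i in range(n_cells)]
    df["core_id"] = df["case_id"].astype(str) + "_" + df["region"].astype(str)
    for j, m in enumerate(markers):
        df[m] = intensities[order, j]
    truth = pd.DataFrame({
        "cell_id": df["cell_id"],
        "case_id": df["case_id"],
        "true_subclass": sub_arr[order],
    })
    return CellTable(panel=panel, df=df), truth


def _simulate_clinical(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    case_truth: pd.DataFrame,
    *,
    all_rectal: bool = False,
    treatment_group: np.ndarray | None = None,
) -> pd.DataFrame:
    n = len(case_truth)
    age = np.clip(rng.normal(69.0, 11.0, size=n), 30.0, 95.0)
    sex = np.where(rng.random(n) < 0.54, "M", "F")
    if all_rectal:
        location = np.repeat("rectum", n)
    else:
        sites = ["caecum", "ascending_colon", "flexura_hepatica", "transverse_colon",
                 "flexura_lienalis", "descending_colon", "sigmoid_colon", "rectum"]
        probs = np.array([0.12, 0.14, 0.04, 0.06, 0.03, 0.06, 0.22, 0.33])
        location = rng.choice(sites, size=n, p=probs / probs.sum())
    stage = rng.choice(["I", "II", "III", "IV"], size=n,
                       p=[0.11, 0.15, 0.59, 0.15])
    pT = rng.choice([1, 2, 3, 4], size=n, p=[0.1, 0.2, 0.55, 0.15])
    pN = rng.choice([0, 1, 2], size=n, p=[0.45, 0.35, 0.2])
    inflamed = case_truth["archetype"].to_numpy() == "inflamed"
    msi_p = np.where(inflamed, 0.25, 0.08)
    msi = np.where(rng.random(n) < msi_p, "MSI-H", "MSS")
    msi = np.where(rng.random(n) < 0.05, "unknown", msi)
    grade = rng.choice(["low", "moderate", "high"], size=n, p=[0.2, 0.6, 0.2])
    surgery = np.where(rng.random(n) < 0.15, "acute", "elective")
    adjuvant = (rng.random(n) < 0.4).astype(int)
    if treatment_group is None:
        treatment_group = np.repeat("naive", n)

    # survival: exponential proportional hazards on true CD8/M2 indicators
    loghr = (np.log(cfg.hr_cd8) * case_truth["cd8_high"].to_numpy()
             + np.log(cfg.hr_m2) * case_truth["m2_high"].to_numpy())
    h = cfg.baseline_hazard * np.exp(loghr)
    t_death = rng.exponential(1.0 / h)
    t_recur = rng.exponential(1.0 / (h * cfg.recurrence_hazard_mult))
    censor = rng.uniform(cfg.censor_low_days, cfg.censor_high_days, size=n)
    os_time = np.minimum(t_death, censor)
    os_event = (t_death <= censor).astype(int)
    first = np.minimum(t_recur, t_death)
    rfs_time = np.minimum(first, censor)
    rfs_event = (first <= censor).astype(int)

    return pd.DataFrame({
        "case_id": case_truth["case_id"],
        "age_years": age,
        "sex": sex,
        "tumor_location": location,
        "stage": stage,
        "pT": pT,
        "pN": pN,
        "msi_status": msi,
        "grade": grade,
        "treatment_group": treatment_group,
        "surgery_type": surgery,
        "adjuvant_treatment": adjuvant,
        "os_time_days": os_time,
        "os_event": os_event,
        "rfs_time_days": rfs_time,
        "rfs_event": rfs_event,
    })


def _case_truth(
    cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    n = cfg.n_cases
    archetype = rng.random(n) < cfg.inflamed_fraction
    latent = rng.normal(0.0, 1.0, size=n)
    df = pd.DataFrame({
        "case_id": _case_ids(n),
        "archetype": np.where(archetype, "inflamed", "desert"),
        "latent": latent,
    })
    return df, archetype.astype(float), latent


def _finalize_truth(
    case_truth: pd.DataFrame, expected: pd.DataFrame
) -> pd.DataFrame:
    """Attach true CD8/M2 high-vs-low indicators (case mean density > cohort median)."""
    for subclass, col in (("CD8_sp", "cd8_high"), ("M2", "m2_high")):
        mean_d = (expected[expected["subclass"] == subclass]
                  .groupby("case_id")["density"].mean())
        med = mean_d.median() if len(mean_d) else 0.0
        ind = (mean_d > med).astype(int)
        case_truth = case_truth.merge(
            ind.rename(col).reset_index(), on="case_id", how="left"
        )
        case_truth[col] = case_truth[col].fillna(0).astype(int)
    return case_truth


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    *,
    rules: RuleSet | None = None,
) -> SimulatedCohort:
    """Generate a full synthetic cohort; deterministic given (config, seed)."""
    if seed is None:
        raise ConfigError("an explicit integer seed is required")
    cfg = config or GeneratorConfig()
    rules = rules or load_default_rules()
    rng = np.random.default_rng(seed)

    case_truth, archetype, latent = _case_truth(cfg, rng)
    expected = _draw_expected_densities(cfg, rng, archetype, latent)
    areas = _draw_areas(cfg, rng, cfg.n_cases)

    cells: dict[str, CellTable] = {}
    cell_truth: dict[str, pd.DataFrame] = {}
    for panel_name in PANELS:
        table, truth = _synthesize_panel_cells(
            cfg, rng, panel_name, expected, areas, rules
        )
        cells[panel_name] = table
        cell_truth[panel_name] = truth

    case_truth = _finalize_truth(case_truth, expected)
    clinical = _simulate_clinical(cfg, rng, case_truth)

    return SimulatedCohort(
        cells=cells,
        areas=areas,
        clinical=clinical,
        truth=GroundTruth(
            case_truth=case_truth,
            expected_densities=expected,
            cell_truth=cell_truth,
            config=cfg,
        ),
    )


def null_config(config: GeneratorConfig | None = None) -> GeneratorConfig:
    """A copy of *config* with every archetype and survival effect zeroed."""
    cfg = config or GeneratorConfig()
    flat = {
        name: replace(p, inflamed_shift=0.0)
        for name, p in cfg.subclass_params.items()
    }
    return replace(cfg, subclass_params=flat, hr_cd8=1.0, hr_m2=1.0)


def simulate_null_cohort(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    *,
    rules: RuleSet | None = None,
) -> SimulatedCohort:
    """A cohort with no archetype separation and no survival effects."""
    return simulate_cohort(null_config(config), seed, rules=rules)


def simulate_rectal_treatment(
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    *,
    rules: RuleSet | None = None,
) -> SimulatedCohort:
    """Three-group rectal cohort: naive, RT + immediate surgery, delayed surgery.

    Radiation depletes most subclasses in the immediate-surgery group
    (``depletion_factor``); the delayed group repopulates to
    ``recovery_factor`` of naive levels, except M1 macrophages which stay
    depleted when ``m1_persistent_depletion`` is set.  CD4/CD8 single
    positives and B cells are stable across groups.
    """
    if seed is None:
        raise ConfigError("an explicit integer seed is required")
    cfg = config or GeneratorConfig()
    rules = rules or load_default_rules()
    n_total = 3 * cfg.n_per_group
    cfg = replace(cfg, n_cases=n_total)
    rng = np.random.default_rng(seed)

    case_truth, archetype, latent = _case_truth(cfg, rng)
    group = np.repeat(["naive", "RT_immediate", "RT_CRT_delayed"], cfg.n_per_group)

    factors: dict[str, np.ndarray] = {}
    for subclass in cfg.subclass_params:
        f = np.ones(n_total)
        if subclass not in TREATMENT_STABLE_SUBCLASSES:
            f[group == "RT_immediate"] = cfg.depletion_factor
            if subclass == "M1" and cfg.m1_persistent_depletion:
                f[group == "RT_CRT_delayed"] = cfg.m1_delayed_factor
            else:
                f[group == "RT_CRT_delayed"] = cfg.recovery_factor
        factors[subclass] = f

    expected = _draw_expected_densities(
        cfg, rng, archetype, latent, group_factors_by_subclass=factors
    )
    areas = _draw_areas(cfg, rng, n_total)

    cells: dict[str, CellTable] = {}
    cell_truth: dict[str, pd.DataFrame] = {}
    for panel_name in PANELS:
        table, truth = _synthesize_panel_cells(
            cfg, rng, panel_name, expected, areas, rules
        )
        cells[panel_name] = table
        cell_truth[panel_name] = truth

    case_truth = _finalize_truth(case_truth, expected)
    clinical = _simulate_clinical(
        cfg, rng, case_truth, all_rectal=True, treatment_group=group
    )

    return SimulatedCohort(
        cells=cells,
        areas=areas,
        clinical=clinical,
        truth=GroundTruth(
            case_truth=case_truth.assign(treatment_group=group),
            expected_densities=expected,
            cell_truth=cell_truth,
            config=cfg,
        ),
    )


def simulate_survival_cohort(
    n: int,
    *,
    hr: float = 0.64,
    frac_high: float = 0.5,
    baseline_hazard: float = np.log(2) / 1500.0,
    censor_hazard_mult: float = 1.2,
    seed: int,
) -> pd.DataFrame:
    """A minimal proportional-hazards cohort for estimator calibration.

    A binary "high" indicator (e.g. CD8-high) carries true hazard ratio
    *hr*; censoring is exponential with ``censor_hazard_mult`` times the
    baseline hazard, giving roughly 40% observed events at the default.
    """
    rng = np.random.default_rng(seed)
    high = (rng.random(n) < frac_high).astype(float)
    h = baseline_hazard * hr ** high
    t = rng.exponential(1.0 / h)
    c = rng.exponential(1.0 / (censor_hazard_mult * baseline_hazard), size=n)
    return pd.DataFrame({
        "time": np.minimum(t, c),
        "event": (t <= c).astype(int),
        "high": high,
    })


# ---------------------------------------------------------------------------
# Writing a cohort to disk
# ---------------------------------------------------------------------------


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write all cohort tables (and the ground truth) as CSV; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for panel, table in cohort.cells.items():
        p = out / f"cells_{panel}.csv"
        write_cell_table(table, p)
        paths[f"cells_{panel}"] = p
    paths["areas"] = out / "areas.csv"
    write_area_table(cohort.areas, paths["areas"])
    paths["clinical"] = out / "clinical.csv"
    write_clinical_table(cohort.clinical, paths["clinical"])
    paths["case_truth"] = out / "truth_cases.csv"
    cohort.truth.case_truth.to_csv(paths["case_truth"], index=False,
                                   na_rep="NA", float_format="%.6g")
    paths["expected_densities"] = out / "truth_expected_densities.csv"
    cohort.truth.expected_densities.to_csv(
        paths["expected_densities"], index=False, na_rep="NA", float_format="%.6g"
    )
    for panel, truth in cohort.truth.cell_truth.items():
        p = out / f"truth_cells_{panel}.csv"
        truth.to_csv(p, index=False)
        paths[f"truth_cells_{panel}"] = p
    cfg = cohort.truth.config
    resolved = {
        "n_cases": cfg.n_cases,
        "inflamed_fraction": float(cfg.inflamed_fraction),
        "label_noise": float(cfg.label_noise),
        "hr_cd8": float(cfg.hr_cd8),
        "hr_m2": float(cfg.hr_m2),
        "subclasses": {
            name: {"panel": p.panel, "log_median": float(p.log_median),
                   "zero_inflation": float(p.zero_inflation)}
            for name, p in cfg.subclass_params.items()
        },
    }
    paths["config"] = out / "generator_config.yaml"
    with open(paths["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    return paths
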