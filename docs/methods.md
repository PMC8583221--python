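# Methods

`crcimmune` implements an in-situ immune-landscape analysis of colorectal
cancer (CRC) as a tested pipeline, together with a synthetic cohort
generator that provides ground truth for every step. This note documents
the models, the defaults and why, and what the synthetic validation does —
and does not — establish.

## The analysis pipeline

### Gating

Segmented cells arrive with one raw fluorescence intensity per panel marker
(three panels: lymphocyte — CD4, CD8, CD20, FoxP3, CD45RO, panCK;
NK/macrophage — CD56, NKp46, CD3, CD68, CD163, panCK; dendritic — CD3,
CD1a, CD208, CD123, CD68, CD15, panCK). A cell is positive for a marker
when its intensity is **strictly greater** than the marker's threshold;
ties are negative. Strictness is a deliberate, tested convention — any
fixed tie rule would do, but it must be single and explicit.

Cells are assigned to one of 15 immune subclasses by ordered Boolean
co-expression rules (`data/rules_default.yaml`): the first rule whose
`all_of`/`any_of`/`none_of` requirements the call vector satisfies wins;
unmatched cells, including every pan-cytokeratin-positive (epithelial)
cell, are labeled `other`. The rule file is data, not code. The shipped
15-subclass scheme is a reconstruction from the panel composition, the
subclass names used in the analyses (CD4/CD8 single positive, CD4/CD8
Treg, CD45RO+ memory subsets, B, NK, NKT, M1/M2, iDC/mDC/pDC, myeloid)
and standard marker biology; users with a different scheme override the
file. Two conventions were genuinely open and are fixed here: "single
positive" T cells are FoxP3− *and* CD45RO− (so the lymphocyte classes
partition cleanly), and rule precedence is file order (first match wins),
which resolves the remaining overlaps — e.g. CD68+CD15+ dendritic-panel
cells — reproducibly. `validate_rules` audits any rule set by exhaustively
enumerating all ≤2⁷ call vectors per panel, reporting order-resolved
overlaps (warnings) and shadowed, unreachable rules (errors).

### Densities

Infiltration is cells per mm² of analyzed tissue area, per subclass, in
the four localizations: {central tumor (CT), invasive margin (IM)} ×
{tumor, stroma} compartments. Counts and areas of multiple cores of the
same (case, region, compartment) are pooled before division. Zero vs
missing is strict: an area record with no cells is a true density of 0; a
missing area record is a missing density. Localizations contributing less
than `min_area_mm2` (default 0.01 mm²) analyzed area are treated as
missing to guard against near-zero denominators. Areas are per panel,
since panels come from different sections. The cube-root transform is
provided for display of the heavily right-skewed densities.

### Immune scores

For each subclass, a case's density in each localization is dichotomized
at the cohort median of that localization — 1 if **strictly above**, else
0 — and the four indicators summed into a 0–4 score. Strict dichotomization
matters for zero-inflated subclasses: when most cases are negative the
median is 0, and a ≥ rule would label the majority-negative group "high".
Scores are complete-case (any missing localization → missing score).
Medians default to the cohort being scored (the therapy-naïve analysis
set); a frozen median table can be supplied to score, e.g., treated rectal
cases against a naïve reference. Scores depend only on within-column
ranks, so any monotone re-scaling of densities (units, transforms) leaves
them unchanged — a tested invariant.

### Statistics

* **Spearman correlation** between subclass scores, midrank ties,
  pairwise-complete; constant columns are undefined and flagged.
* **Ward clustering** of the complete-case score matrix: the minimum-
  variance criterion on Euclidean distances (the `ward.D2`-equivalent
  formulation — documented because the two R Ward variants differ).
  Scores are not standardized: they already share the 0–4 scale.
* **Mann–Whitney U**: exact by enumeration when both samples are ≤8 and
  tie-free, otherwise the normal approximation with tie and continuity
  corrections.
* **Wilcoxon signed-rank, Pratt method** for paired comparisons: zero
  differences are ranked then dropped from the statistic; asymptotic
  normal p with zero/tie-adjusted variance. The reported statistic is the
  positive-rank sum W⁺. The stroma-vs-tumor compartment contrast is a
  case-wise (paired) comparison and uses this test.
* **Benjamini–Hochberg** step-up q-values; one family per reported
  analysis (the 15 subclass tests of one panel/endpoint), not a global
  family.
* **Pearson Chi-square** without continuity correction (tables are not
  all 2×2).
* **Cox proportional hazards** by partial likelihood with the **Efron**
  tie correction (day-resolution times produce heavy ties), Wald 95% CI
  and p. The immune score enters either as a continuous 0–4 covariate or
  dichotomized at its median (config choice; recovery demonstrations use
  the binary coding). Constant covariates report HR 1 by convention;
  non-convergence (monotone likelihood) is flagged on the estimate, not
  raised. OS is time to death from any cause; RFS is the composite of
  progression and death, whichever first, censored at last follow-up.

The composite `analysis_recipes` reproduces the full analysis set:
cluster-by-covariate Chi-square enrichment, univariable OS in
therapy-naïve cases, univariable + multivariable RFS in stage I–III colon
cancer (adjusted for pT, pN, differentiation grade, age, surgery type,
adjuvant treatment), stage-IV OS, and the rectal three-group density
comparisons. Recipes whose inputs are absent are skipped with a log entry.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions.

* **Archetypes.** Each case is immune-"inflamed" with probability
  145/373 ≈ 0.389, else "desert". Inflamed cases have T-lineage log
  densities shifted up by 3.0 (single-positive and memory classes), 2.6
  (Tregs), 2.0 (B cells); M1 shifts mildly with the inflamed state (+0.4)
  and M2/myeloid/mDC/pDC mildly against it. The shifts are set so that the
  two phenotypes are clearly separated in score space (k=2 Ward recovers
  the archetype for ≳97% of cases), which is the regime the analysis
  describes; a shared latent "immune activation" factor (loading 0.3 on
  T classes) adds within-archetype correlation between T subclasses
  without specifying a full covariance. Together the mixture and the
  latent factor reproduce high inter-T-cell score correlations (Spearman
  ρ ≈ 0.6–0.7).
* **Densities.** Per-case expected densities are lognormal (per-subclass
  log-medians anchored at realistic magnitudes, e.g. CD8 single positive
  314 and M1 431 cells/mm² for a desert-archetype CT stroma; σ = 0.8–1.0),
  with per-localization jitter (σ = 0.25), a tumor/stroma ratio per
  subclass (<1 = stroma-enriched for most; 1.8 for CD8 single positive
  and myeloid cells, the two tumor-enriched classes), a CT-vs-IM excess
  for T cells (+0.2), and a cap at 12,000 cells/mm². NK and NKT are
  zero-inflated: a case is fully negative with probability 0.77 / 0.81.
* **Cells.** Counts are Poisson(density × area) per localization; areas
  are lognormal around 0.25 mm² per (case, region, compartment, panel),
  scalable by `area_scale` for desk-scale runs. Positions are uniform
  within the (abstracted) compartment — no downstream step uses geometry
  beyond density, so spatial point-pattern realism is out of scope.
* **Intensities.** Each cell's true call vector satisfies its subclass
  rule (one `any_of` member always on, others with probability 0.25);
  intensities are drawn strictly on the correct side of the true
  threshold (log-offset 0.15 plus half-normal spread 0.7). At zero label
  noise gating therefore recovers every cell exactly — by construction,
  which is what makes the end-to-end ground truth exact. `label_noise`
  flips one random marker call per affected cell to emulate imperfect
  phenotyping.
* **Survival.** Exponential proportional hazards with baseline
  log(2)/1500 per day, driven by true case-level CD8-high (HR 0.64) and
  M2-high (HR 1.50) indicators (expected density above the cohort
  median); uniform administrative censoring on 180–3600 days. The
  lightweight `simulate_survival_cohort` (binary covariate, exponential
  censoring at 1.2× the baseline hazard → ≈40% events) is used for
  estimator calibration.
* **Treatment design.** The three-group rectal cohort (26 cases per
  group) multiplies expected densities by 0.3 in the RT-with-immediate-
  surgery group and restores them (factor 1.0) in the delayed group,
  except CD4/CD8 single positives and B cells (stable throughout) and M1
  (persistently depleted at 0.5 in the delayed group when enabled).

Determinism: every public entry point requires an explicit seed and is
byte-reproducible given (config, seed).

## What the synthetic validation shows — and does not

Passing tests establish that the pipeline's arithmetic, conventions and
estimators are correct: gating matches an independent first-match oracle
on every call vector; densities and scores obey their invariants; the
exact Mann–Whitney equals full enumeration; BH equals the step-up formula;
Ward equals exhaustive-search agglomeration; the Cox estimator recovers a
known HR of 0.64 with nominal CI coverage; and injected effects (CD8
protective, M2 adverse, inflamed/desert separation, radiation depletion/
repopulation) propagate through the full pipeline in the right direction.
They do **not** establish anything about real staining data: the generator
has no segmentation error, no staining artifacts or necrosis, no spatial
structure, conditionally independent marker intensities given the
subclass, and lognormal densities chosen for plausibility (the underlying
study reports only medians/means/ranges, not distributions). Thresholds on
real data remain a manual, per-batch calibration problem that this package
deliberately takes as input.

## Numerical conventions and degenerate inputs

Sample medians use the mean-of-middle-two convention for even n; columns
with fewer than 2 non-missing cases yield missing medians and scores.
Densities with analyzed area below 0.01 mm² are missing. All-zero
difference vectors make the signed-rank test undefined (error, not NaN).
Zero-event Cox models are errors; constant covariates give HR 1. Ward
heights are non-decreasing (reducibility); k must lie in [1, n].
Problem sizes in the shipped analysis scripts and acceptance script
(cohorts of 250–373 cases at `area_scale` 0.4, 100 Cox replicates at
n = 1000) are chosen so a full run completes in minutes on one CPU while
keeping Monte-Carlo error well below the effects being demonstrated.

## Known limitations

* The 15-subclass rule file is a plausible reconstruction, not a
  transcription of the original scheme; it is configuration, not code.
* Immune-score medians may legitimately be computed on different
  reference sets (all cases vs therapy-naïve); the default is the set
  being scored, and frozen median tables make any other choice explicit.
* Single-cohort hazard-ratio estimates at n ≈ 373 carry sampling error of
  roughly ±0.2 on the log scale; only the replicate-averaged calibration
  pins the estimator down tightly.
* No proportional-hazards diagnostics beyond convergence checks, no
  competing risks, no spatial statistics beyond density.
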