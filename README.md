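# crcimmune

Analysis pipeline for the in-situ immune landscape of colorectal cancer
(CRC), built for multiplex-immunofluorescence studies that phenotype
single cells on tissue microarrays. Starting from per-cell marker
intensities, the pipeline

1. **gates** each cell into one of 15 immune subclasses (or `other`) via
   threshold positivity calls and ordered Boolean co-expression rules
   (three antibody panels: lymphocyte, NK/macrophage, dendritic);
2. **quantifies** densities (cells/mm²) in the four localizations —
   {central tumor, invasive margin} × {tumor, stroma} compartments;
3. **scores** each subclass per case on a 0–4 scale: each localization's
   density is dichotomized at the cohort median (1 if strictly above) and
   the four indicators summed;
4. **clusters** the score matrix (Ward, Euclidean) into immune-'inflamed'
   and immune-'desert' phenotypes and correlates scores across subclasses
   (Spearman);
5. associates scores with **survival** via Cox proportional-hazards models
   (OS and recurrence-free survival; univariable and covariate-adjusted;
   Efron ties; Benjamini–Hochberg q-values per 15-subclass family).

Because real cohorts of this kind are rarely public, the package includes
a first-class **synthetic cohort generator** that emulates the assumed
statistical structure — two-archetype mixture, correlated lognormal
densities, NK/NKT zero-inflation (77%/81% negative cases), stromal
enrichment, proportional-hazards survival driven by CD8 (protective,
HR 0.64) and M2 macrophage (adverse, HR 1.50) scores, and a three-group
rectal radiotherapy design — with full ground truth, so every step is
testable end to end. See `docs/methods.md` for the models and defaults.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (`python analysis/01_simulate_cohort.py --seed 1`, then 02…07).
Highlights of an actual run at seed 1 (373 cases, ~1.9M cells):

```
02: lymphocyte: 1656683 cells gated, 100.00% match generator truth
03: fully negative cases: NK 80%, NKT 86%
    stroma-enriched (q<0.05): 11 subclasses
    tumor-enriched (q<0.05): ['CD8_sp', 'myeloid']
04: mean Spearman rho among T-cell scores: 0.70
05: two phenotype clusters: sizes [155, 218] (minority = 41.6%)
    agreement with true archetypes: 99.2%
06: os_univariable: CD8_sp HR 0.64 [0.48-0.85], q = 0.015
    rfs_multivariable: M2 HR 1.62 [1.17-2.23], q = 0.056
07: naive_vs_RT_immediate: 10/15 subclasses significantly lower than naive
```

Reading this: gating exactly recovers the generator's cell labels (the
intensities are noise-free by default); NK/NKT negativity and the
two-cluster split match the configured study conditions (0.77/0.81
negativity, 38.9% inflamed); a high CD8 single-positive immune score
roughly halves the death hazard while a high M2 score raises it — the
effects the generator injected (HR 0.64 and 1.50).

The same steps are scriptable from the shell (`crcimmune simulate|gate|
quantify|score|cluster|correlate|compare|survival|report`) or callable as
a library:

```python
from crcimmune import pipeline, synthetic
cohort = synthetic.simulate_cohort(seed=1)
result = pipeline.run_pipeline(cohort.cells, cohort.areas)
result.scores          # cases x 15 integer immune scores
result.cluster.sizes   # inflamed/desert cluster sizes
```

## Layout

```
src/crcimmune/     io_model, gating, quantify, scoring, stats, synthetic,
                   pipeline, cli  (+ data/: default rules & thresholds)
analysis/          numbered narrative drivers (simulate ... rectal treatment)
tests/             pytest suite incl. oracle-based acceptance checks
scripts/           acceptance.py
docs/methods.md    models, defaults, limitations
```
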