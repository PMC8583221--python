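#!/usr/bin/env python
"""Radiation-induced depletion and repopulation in rectal cancer.

Simulates the three-group rectal design (primary surgery, short-course RT
with immediate surgery, RT/CRT with delayed surgery), runs the full gating
and quantification pipeline, and compares per-subclass pooled densities
between groups (Mann-Whitney, BH-adjusted per contrast).  The expected
signature: most subclasses depleted right after radiation, recovered in the
delayed group — except M1 macrophages, which stay depleted.
"""
import argparse
from dataclasses import replace
from pathlib import Path

from crcimmune import pipeline
from crcimmune.quantify import pooled_case_density
from crcimmune.stats import treatment_group_comparisons
from crcimmune.synthetic import GeneratorConfig, simulate_rectal_treatment


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cfg = replace(GeneratorConfig(), area_scale=0.4, n_per_group=26)
    cohort = simulate_rectal_treatment(cfg, seed=args.seed)
    _, densities = pipeline.gate_and_quantify(cohort.cells, cohort.areas)
    groups = cohort.clinical.groupby("treatment_group")["case_id"].apply(list)
    out = treatment_group_comparisons(pooled_case_density(densities), groups)
    out.to_csv(args.out_dir / "rectal_comparisons.csv", index=False,
               float_format="%.6g")

    for contrast in out["contrast"].unique():
        sub = out[out.contrast == contrast]
        sig = sub.loc[(sub.q < 0.05) & (sub.direction > 0), "subclass"]
        print(f"{contrast}: {len(sig)}/{len(sub)} subclasses significantly "
              f"lower than naive (q<0.05): {sorted(sig)}")
    m1 = out[(out.contrast == "naive_vs_delayed")
             & (out.subclass == "M1")].iloc[0]
    print(f"M1 in delayed group (persistent depletion): "
          f"direction {m1.direction:+.0f}, q = {m1.q:.3f}")


if __name__ == "__main__":
    main()
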