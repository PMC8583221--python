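#!/usr/bin/env python
"""Immune scores and survival: univariable and multivariable Cox models.

Runs the survival analysis set on the scored cohort: univariable OS per
subclass score in therapy-naive cases, univariable + multivariable RFS in
stage I-III colon cancer (adjusted for pT, pN, differentiation, age,
surgery type and adjuvant treatment), and stage-IV OS; each family of 15
subclass models is BH-adjusted.  Scores enter dichotomized at the cohort
median.
"""
import argparse
from pathlib import Path

from crcimmune.io_model import read_clinical_table, read_score_table
from crcimmune.stats import CohortData, analysis_recipes


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scores", type=Path, default=Path("results/scores.csv"))
    ap.add_argument("--clinical", type=Path,
                    default=Path("results/cohort/clinical.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    wide = read_score_table(args.scores).pivot_table(
        index="case_id", columns="subclass", values="score", dropna=False
    )
    clinical = read_clinical_table(args.clinical)
    bundle = analysis_recipes(CohortData(clinical=clinical, scores=wide),
                              coding="dichotomized")

    for name, df in (("os_univariable", bundle.os_univariable),
                     ("rfs_univariable", bundle.rfs_univariable),
                     ("rfs_multivariable", bundle.rfs_multivariable),
                     ("stage4_os", bundle.stage4_os)):
        if df is None:
            print(f"{name}: skipped")
            continue
        df.to_csv(args.out_dir / f"{name}.csv", index=False, float_format="%.6g")
        sub = df.set_index("term")
        for term in ("CD8_sp", "M2"):
            if term in sub.index:
                r = sub.loc[term]
                print(f"{name}: {term} HR {r.hr:.2f} "
                      f"[{r.ci_low:.2f}-{r.ci_high:.2f}], q = {r.q:.3f}")
    if bundle.skipped:
        print("skipped:", "; ".join(bundle.skipped))


if __name__ == "__main__":
    main()
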