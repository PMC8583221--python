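#!/usr/bin/env python
"""Ward clustering of immune scores into inflamed/desert phenotypes.

Clusters complete-score cases at k=2, compares the labels with the
generator's true archetypes, and tests cluster enrichment of clinical
covariates (Chi-square, BH-adjusted).
"""
import argparse
from pathlib import Path

import pandas as pd

from crcimmune.io_model import read_clinical_table, read_score_table
from crcimmune.scoring import complete_cases
from crcimmune.stats import CohortData, analysis_recipes, silhouette, ward_cluster


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scores", type=Path, default=Path("results/scores.csv"))
    ap.add_argument("--clinical", type=Path,
                    default=Path("results/cohort/clinical.csv"))
    ap.add_argument("--truth", type=Path,
                    default=Path("results/cohort/truth_cases.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    wide = read_score_table(args.scores).pivot_table(
        index="case_id", columns="subclass", values="score", dropna=False
    )
    scores = complete_cases(wide)
    result = ward_cluster(scores, 2)
    result.labels.rename("cluster").rename_axis("case_id").reset_index().to_csv(
        args.out_dir / "clusters.csv", index=False
    )
    sizes = result.sizes
    print(f"two phenotype clusters: sizes {sizes.tolist()} "
          f"(minority = {100 * sizes.min() / sizes.sum():.1f}%)")
    print(f"mean silhouette at k=2: {silhouette(scores, result.labels):.3f}")

    if args.truth.exists():
        truth = pd.read_csv(args.truth).set_index("case_id")
        arch = truth.loc[result.labels.index, "archetype"]
        a = (((result.labels == 1) & (arch == "inflamed"))
             | ((result.labels == 2) & (arch == "desert"))).mean()
        agree = max(a, 1 - a)
        print(f"agreement with true archetypes: {100 * agree:.1f}%")

    clinical = read_clinical_table(args.clinical)
    bundle = analysis_recipes(
        CohortData(clinical=clinical, scores=wide, cluster_labels=result.labels)
    )
    if bundle.enrichment is not None:
        bundle.enrichment.to_csv(args.out_dir / "cluster_enrichment.csv",
                                 index=False, float_format="%.6g")
        sig = bundle.enrichment.loc[bundle.enrichment.q < 0.05, "covariate"]
        print(f"cluster-enriched covariates (q<0.05): {sig.tolist()}")


if __name__ == "__main__":
    main()
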