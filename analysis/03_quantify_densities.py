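#!/usr/bin/env python
"""Densities in the four localizations and the stroma-vs-tumor contrast.

Computes cells/mm^2 per (case, subclass, region CT/IM, compartment
tumor/stroma), summarizes each subclass (median/mean density, share of
fully negative cases), and runs the case-wise paired stroma-vs-tumor
comparison with BH correction.
"""
import argparse
from pathlib import Path

import pandas as pd

from crcimmune.io_model import (
    PANELS,
    load_default_rules,
    read_area_table,
    write_density_table,
)
from crcimmune.quantify import compute_densities, density_matrix, localization_summary
from crcimmune.stats import compartment_comparisons


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--gated-dir", type=Path, default=Path("results/gated"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    rules = load_default_rules()
    areas = read_area_table(args.cohort_dir / "areas.csv")
    parts = []
    for panel in PANELS:
        phenotyped = pd.read_csv(args.gated_dir / f"gated_{panel}.csv")
        subclasses = [r.subclass for r in rules.for_panel(panel)]
        parts.append(compute_densities(phenotyped, areas, subclasses, panel))
    densities = pd.concat(parts, ignore_index=True)
    write_density_table(densities, args.out_dir / "densities.csv")

    matrix = density_matrix(densities)
    summ = localization_summary(matrix)
    summ.to_csv(args.out_dir / "density_summary.csv", index=False,
                float_format="%.6g")
    pooled = summ.groupby("subclass")[["median", "mean"]].mean().round(0)
    for sub in ("CD8_sp", "M1"):
        print(f"{sub}: median ~{pooled.loc[sub, 'median']:.0f}, "
              f"mean ~{pooled.loc[sub, 'mean']:.0f} cells/mm^2")
    neg = summ.groupby("subclass")["fraction_zero"].first()
    print(f"fully negative cases: NK {100 * neg['NK']:.0f}%, "
          f"NKT {100 * neg['NKT']:.0f}%")

    cc = compartment_comparisons(matrix)
    cc.to_csv(args.out_dir / "stroma_vs_tumor.csv", index=False,
              float_format="%.6g")
    stroma = cc.loc[(cc.q < 0.05) & (cc.direction > 0), "subclass"].tolist()
    tumor = cc.loc[(cc.q < 0.05) & (cc.direction < 0), "subclass"].tolist()
    print(f"stroma-enriched (q<0.05): {len(stroma)} subclasses")
    print(f"tumor-enriched (q<0.05): {tumor}")


if __name__ == "__main__":
    main()
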