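"""End-to-end orchestration: gate -> quantify -> score -> cluster -> survival.

Thin composition of the per-step modules, used by the analysis scripts, the
command-line interface and the test suite.  Each step's computation lives in
its own module; this file only wires them together deterministically.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import gating, quantify, scoring, stats
from .gating import RuleSet
from .io_model import CellTable, ThresholdSet, load_default_rules, load_default_thresholds


@dataclass
class PipelineResult:
    phenotyped: dict[str, pd.DataFrame]   # panel -> gated cell table
    densities: pd.DataFrame               # long, all panels pooled
    density_matrix: pd.DataFrame          # cases x (subclass, region, compartment)
    medians: pd.Series
    scores: pd.DataFrame                  # cases x 15 subclasses
    cluster: stats.ClusterResult | None = None
    correlation: stats.CorrelationMatrix | None = None


def gate_and_quantify(
    cells: dict[str, CellTable],
    areas: pd.DataFrame,
    *,
    rules: RuleSet | None = None,
    thresholds: dict[str, ThresholdSet] | None = None,
    include_other: bool = False,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Gate every panel's cells and compute the pooled long density table."""
    rules = rules or load_default_rules()
    thresholds = thresholds or load_default_thresholds()
    phenotyped: dict[str, pd.DataFrame] = {}
    density_parts = []
    for panel_name, table in cells.items():
        ph, _counts = gating.gate_table(table, thresholds[panel_name], rules)
        phenotyped[panel_name] = ph
        panel_subclasses = [r.subclass for r in rules.for_panel(panel_name)]
        density_parts.append(quantify.compute_densities(
            ph, areas, panel_subclasses, panel_name, include_other=include_other,
        ))
    densities = pd.concat(density_parts, ignore_index=True)
    return phenotyped, densities


def run_pipeline(
    cells: dict[str, CellTable],
    areas: pd.DataFrame,
    *,
    rules: RuleSet | None = None,
    thresholds: dict[str, ThresholdSet] | None = None,
    medians: pd.Series | None = None,
    cluster_k: int | None = 2,
    correlate: bool = False,
) -> PipelineResult:
    """Run gating through scoring (and optionally clustering/correlation)."""
    phenotyped, densities = gate_and_quantify(
        cells, areas, rules=rules, thresholds=thresholds
    )
    matrix = quantify.density_matrix(densities)
    med = medians if medians is not None else scoring.compute_medians(matrix)
    scores = scoring.score_matrix(matrix, med)
    result = PipelineResult(
        phenotyped=phenotyped,
        densities=densities,
        density_matrix=matrix,
        medians=med,
        scores=scores,
    )
    complete = scoring.complete_cases(scores)
    if cluster_k is not None and len(complete) >= cluster_k:
        result.cluster = stats.ward_cluster(complete, cluster_k)
    if correlate:
        result.correlation = stats.spearman_matrix(scores)
    return result
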