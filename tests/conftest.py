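from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from crcimmune import pipeline
from crcimmune.io_model import (
    PANELS,
    CellTable,
    load_default_rules,
    load_default_thresholds,
)
from crcimmune.synthetic import GeneratorConfig, simulate_cohort


@pytest.fixture(scope="session")
def rules():
    return load_default_rules()


@pytest.fixture(scope="session")
def thresholds():
    return load_default_thresholds()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest full synthetic cohort shared by read-only tests."""
    cfg = replace(GeneratorConfig(), n_cases=60, area_scale=0.3)
    return simulate_cohort(cfg, seed=912)


@pytest.fixture(scope="session")
def small_result(small_cohort):
    return pipeline.run_pipeline(small_cohort.cells, small_cohort.areas)


def make_cells(panel_name: str, cells: list[tuple[str, list[str]]]) -> CellTable:
    """Hand-build a cell table: (cell_id, positive markers) per cell.

    Positive markers get intensity 2.0, negatives 0.2 (default thresholds
    are 1.0 everywhere).
    """
    panel = PANELS[panel_name]
    rows = []
    for i, (cell_id, positives) in enumerate(cells):
        row = {
            "cell_id": cell_id,
            "case_id": "caseA",
            "core_id": "caseA_CT",
            "region": "CT",
            "compartment": "stroma",
            "x_um": float(i),
            "y_um": float(i),
        }
        for m in panel.markers:
            row[m] = 2.0 if m in positives else 0.2
        rows.append(row)
    df = pd.DataFrame(rows, columns=[
        "cell_id", "case_id", "core_id", "region", "compartment",
        "x_um", "y_um", *panel.markers,
    ])
    return CellTable(panel=panel, df=df)


#: One hand-built cell per subclass (all three panels) plus one epithelial
#: "other" cell — 16 cells in total, each uniquely satisfying its rule.
SUBCLASS_FIXTURE = {
    "lymphocyte": [
        ("c_cd4sp", ["CD4"]),
        ("c_cd8sp", ["CD8"]),
        ("c_cd4treg", ["CD4", "FoxP3"]),
        ("c_cd8treg", ["CD8", "FoxP3"]),
        ("c_cd4mem", ["CD4", "CD45RO"]),
        ("c_cd8mem", ["CD8", "CD45RO"]),
        ("c_bcell", ["CD20"]),
        ("c_other", ["panCK", "CD4"]),   # epithelial: panCK+ blocks everything
    ],
    "nk_macrophage": [
        ("c_nk", ["CD56"]),
        ("c_nkt", ["NKp46", "CD3"]),
        ("c_m1", ["CD68"]),
        ("c_m2", ["CD68", "CD163"]),
    ],
    "dendritic": [
        ("c_idc", ["CD1a"]),
        ("c_mdc", ["CD208"]),
        ("c_pdc", ["CD123"]),
        ("c_myeloid", ["CD15"]),
    ],
}

EXPECTED_FIXTURE_LABELS = {
    "c_cd4sp": "CD4_sp", "c_cd8sp": "CD8_sp", "c_cd4treg": "CD4_Treg",
    "c_cd8treg": "CD8_Treg", "c_cd4mem": "CD4_CD45RO", "c_cd8mem": "CD8_CD45RO",
    "c_bcell": "B_cell", "c_other": "other",
    "c_nk": "NK", "c_nkt": "NKT", "c_m1": "M1", "c_m2": "M2",
    "c_idc": "iDC", "c_mdc": "mDC", "c_pdc": "pDC", "c_myeloid": "myeloid",
}
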