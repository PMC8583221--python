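import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crcimmune.errors import ConfigError
from crcimmune.gating import (
    GatingRule,
    RuleSet,
    apply_thresholds,
    assign_phenotype,
    assign_phenotypes,
    gate_table,
    validate_rules,
)
from crcimmune.io_model import PANELS, CellTable
from conftest import EXPECTED_FIXTURE_LABELS, SUBCLASS_FIXTURE, make_cells
import oracles


class TestThresholding:
    @pytest.mark.parametrize("intensity,expected", [
        (5.0, False),    # tie is negative: strict inequality
        (5.01, True),
        (0.0, False),
    ])
    def test_positivity_is_strictly_greater_than(self, intensity, expected, thresholds):
        table = make_cells("lymphocyte", [("a", [])])
        table.df["CD4"] = intensity
        thr = thresholds["lymphocyte"]
        thr = type(thr)("lymphocyte", {**thr.thresholds, "CD4": 5.0})
        calls = apply_thresholds(table, thr)
        assert bool(calls.loc[0, "CD4"]) is expected

    def test_all_zero_intensities_are_all_negative(self, thresholds):
        table = make_cells("lymphocyte", [("a", [])])
        for m in table.panel.markers:
            table.df[m] = 0.0
        assert not apply_thresholds(table, thresholds["lymphocyte"]).any().any()

    def test_panel_mismatch_rejected(self, thresholds):
        table = make_cells("lymphocyte", [("a", [])])
        with pytest.raises(ConfigError):
            apply_thresholds(table, thresholds["dendritic"])

    def test_raising_one_threshold_never_gains_positives(self, thresholds):
        rng = np.random.default_rng(3)
        table = make_cells("lymphocyte", [(f"c{i}", []) for i in range(200)])
        for m in table.panel.markers:
            table.df[m] = rng.uniform(0, 2, 200)
        base = apply_thresholds(table, thresholds["lymphocyte"])["CD4"].sum()
        for higher in (1.1, 1.5, 3.0):
            thr = type(thresholds["lymphocyte"])(
                "lymphocyte", {**thresholds["lymphocyte"].thresholds, "CD4": higher}
            )
            assert apply_thresholds(table, thr)["CD4"].sum() <= base


class TestAssignment:
    def test_each_subclass_fixture_cell_gets_its_label(self, rules, thresholds):
        for panel, cells in SUBCLASS_FIXTURE.items():
            table = make_cells(panel, cells)
            phenotyped, _ = gate_table(table, thresholds[panel], rules)
            got = dict(zip(phenotyped.cell_id, phenotyped.subclass))
            for cell_id, _pos in cells:
                assert got[cell_id] == EXPECTED_FIXTURE_LABELS[cell_id]

    def test_cd8_foxp3_cell_is_cd8_treg(self, rules):
        calls = {m: False for m in PANELS["lymphocyte"].markers}
        calls.update(CD8=True, FoxP3=True)
        assert assign_phenotype(calls, rules, "lymphocyte") == "CD8_Treg"

    def test_macrophage_polarization_split_on_cd163(self, rules):
        base = {m: False for m in PANELS["nk_macrophage"].markers}
        assert assign_phenotype({**base, "CD68": True}, rules, "nk_macrophage") == "M1"
        assert assign_phenotype({**base, "CD68": True, "CD163": True},
                                rules, "nk_macrophage") == "M2"

    def test_all_negative_cell_falls_back_to_other(self, rules):
        calls = {m: False for m in PANELS["lymphocyte"].markers}
        assert assign_phenotype(calls, rules, "lymphocyte") == "other"

    def test_panck_positive_cell_is_never_immune(self, rules):
        # every immune pattern is vetoed by epithelial marker positivity
        for panel_name, pdef in PANELS.items():
            for m in pdef.markers:
                calls = {k: False for k in pdef.markers}
                calls[m] = True
                calls["panCK"] = True
                assert assign_phenotype(calls, rules, panel_name) == "other"

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_vectorized_assignment_matches_brute_force_scan(self, rules, data):
        panel_name = data.draw(st.sampled_from(list(PANELS)))
        pdef = PANELS[panel_name]
        bits = data.draw(st.lists(st.booleans(), min_size=len(pdef.markers),
                                  max_size=len(pdef.markers)))
        calls = dict(zip(pdef.markers, bits))
        specs = [(r.subclass, r.all_of, r.any_of, r.none_of)
                 for r in rules.for_panel(panel_name)]
        expected = oracles.assign_first_match(calls, specs)
        assert assign_phenotype(calls, rules, panel_name) == expected
        df = pd.DataFrame([calls])
        assert assign_phenotypes(df, rules, panel_name).iloc[0] == expected


class TestGateTable:
    def test_counts_partition_the_input(self, rules, thresholds, small_cohort):
        table = small_cohort.cells["nk_macrophage"]
        phenotyped, counts = gate_table(table, thresholds["nk_macrophage"], rules)
        assert counts["n_cells"].sum() == len(table)
        assert phenotyped["subclass"].notna().all()

    def test_concatenated_input_doubles_every_count(self, rules, thresholds):
        table = make_cells("lymphocyte", SUBCLASS_FIXTURE["lymphocyte"])
        doubled = CellTable(
            panel=table.panel,
            df=pd.concat([table.df, table.df], ignore_index=True),
        )
        _, c1 = gate_table(table, thresholds["lymphocyte"], rules)
        _, c2 = gate_table(doubled, thresholds["lymphocyte"], rules)
        merged = c1.merge(c2, on=["core_id", "subclass"], suffixes=("_1", "_2"))
        assert (merged["n_cells_2"] == 2 * merged["n_cells_1"]).all()

    def test_empty_input_gives_empty_counts(self, rules, thresholds):
        table = make_cells("lymphocyte", [])
        phenotyped, counts = gate_table(table, thresholds["lymphocyte"], rules)
        assert len(phenotyped) == 0 and len(counts) == 0

    def test_labels_invariant_to_row_order(self, rules, thresholds, small_cohort):
        table = small_cohort.cells["dendritic"]
        shuffled = CellTable(
            panel=table.panel,
            df=table.df.sample(frac=1, random_state=0).reset_index(drop=True),
        )
        p1, _ = gate_table(table, thresholds["dendritic"], rules)
        p2, _ = gate_table(shuffled, thresholds["dendritic"], rules)
        s1 = p1.set_index("cell_id")["subclass"]
        s2 = p2.set_index("cell_id")["subclass"]
        assert s1.sort_index().equals(s2.sort_index())


class TestRuleValidation:
    def test_default_rule_set_audits_clean(self, rules):
        report = validate_rules(rules)
        assert report.ok
        assert report.unreachable == []
        # overlaps are allowed but must be warnings, resolved by order
        assert all("resolved by order" in w for w in report.warnings)

    def test_duplicate_rule_flagged_unreachable(self):
        r1 = GatingRule("A", "lymphocyte", all_of=("CD4",), none_of=("panCK",))
        r2 = GatingRule("B", "lymphocyte", all_of=("CD4",), none_of=("panCK",))
        report = validate_rules(RuleSet(rules=(r1, r2)))
        assert "B" in report.unreachable
        assert not report.ok

    def test_contradictory_rule_cannot_be_constructed(self):
        with pytest.raises(ConfigError, match="positive and negative"):
            GatingRule("X", "lymphocyte", all_of=("CD4",), none_of=("CD4",))

    def test_panck_required_positive_is_rejected(self):
        with pytest.raises(ConfigError, match="panCK"):
            GatingRule("X", "lymphocyte", all_of=("panCK",))
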