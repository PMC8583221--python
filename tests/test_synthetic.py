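import filecmp
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from crcimmune import pipeline
from crcimmune.errors import ConfigError
from crcimmune.synthetic import (
    GeneratorConfig,
    SubclassParams,
    TREATMENT_STABLE_SUBCLASSES,
    null_config,
    simulate_cohort,
    simulate_null_cohort,
    simulate_rectal_treatment,
    simulate_survival_cohort,
    write_cohort,
)

SMALL = replace(GeneratorConfig(), n_cases=12, area_scale=0.15)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_tables(self, tmp_path):
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        p1 = write_cohort(simulate_cohort(SMALL, seed=5), d1)
        p2 = write_cohort(simulate_cohort(SMALL, seed=5), d2)
        for key in p1:
            assert filecmp.cmp(p1[key], p2[key], shallow=False), key

    def test_different_seed_differs(self):
        c1 = simulate_cohort(SMALL, seed=5)
        c2 = simulate_cohort(SMALL, seed=6)
        assert not c1.clinical.equals(c2.clinical)

    def test_seed_is_mandatory(self):
        with pytest.raises(ConfigError):
            simulate_cohort(SMALL)


class TestConfigValidation:
    def test_infeasible_enrichment_ratio_rejected(self):
        bad = dict(GeneratorConfig().subclass_params)
        bad["NK"] = SubclassParams("nk_macrophage", 1.0, tumor_ratio=-1.0)
        with pytest.raises(ConfigError, match="infeasible"):
            replace(GeneratorConfig(), subclass_params=bad)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ConfigError):
            replace(GeneratorConfig(), inflamed_fraction=1.5)

    def test_zero_cases_gives_empty_tables(self):
        cohort = simulate_cohort(replace(SMALL, n_cases=0), seed=1)
        assert len(cohort.clinical) == 0
        assert all(len(t) == 0 for t in cohort.cells.values())


class TestGroundTruthConsistency:
    def test_zero_label_noise_gating_recovers_every_cell(self, small_cohort,
                                                         small_result):
        for panel, truth in small_cohort.truth.cell_truth.items():
            got = small_result.phenotyped[panel].set_index("cell_id")["subclass"]
            expected = truth.set_index("cell_id")["true_subclass"]
            assert (got == expected.reindex(got.index)).all(), panel

    def test_label_noise_degrades_but_not_destroys_recovery(self, thresholds, rules):
        from crcimmune.gating import gate_table

        noisy_cfg = replace(SMALL, label_noise=0.1, n_cases=15)
        cohort = simulate_cohort(noisy_cfg, seed=8)
        panel = "lymphocyte"
        ph, _ = gate_table(cohort.cells[panel], thresholds[panel], rules)
        got = ph.set_index("cell_id")["subclass"]
        expected = cohort.truth.cell_truth[panel].set_index("cell_id")["true_subclass"]
        acc = (got == expected.reindex(got.index)).mean()
        assert 0.8 < acc < 1.0

    def test_realized_counts_match_expected_densities_poisson(self, small_cohort,
                                                              small_result):
        """Standardized residuals of counts vs lambda*area behave like
        Poisson noise: mean near 0, variance near 1."""
        expected = small_cohort.truth.expected_densities
        dens = small_result.densities.merge(
            expected.rename(columns={"density": "lam"}),
            on=["case_id", "subclass", "region", "compartment"],
        ).dropna(subset=["area_mm2"])
        mu = dens["lam"] * dens["area_mm2"]
        big = mu >= 5.0
        z = (dens.loc[big, "n_cells"] - mu[big]) / np.sqrt(mu[big])
        assert abs(z.mean()) < 0.15
        assert 0.8 < z.std() < 1.25

    def test_nk_nkt_negativity_close_to_configured(self, small_cohort):
        expected = small_cohort.truth.expected_densities
        for sub, p in (("NK", 0.77), ("NKT", 0.81)):
            per_case = expected[expected.subclass == sub].groupby("case_id")[
                "density"].max()
            frac = (per_case == 0).mean()
            n = len(per_case)
            assert abs(frac - p) <= 1.96 * np.sqrt(p * (1 - p) / n) + 1e-9

    def test_intensities_respect_true_thresholds(self, small_cohort):
        thr = small_cohort.truth.config.threshold_truth
        df = small_cohort.cells["lymphocyte"].df
        vals = df[list(small_cohort.cells["lymphocyte"].panel.markers)].to_numpy()
        assert (vals != thr).all()  # strictly off-threshold by construction


class TestNullCohort:
    def test_null_config_zeroes_effects(self):
        cfg = null_config()
        assert all(p.inflamed_shift == 0 for p in cfg.subclass_params.values())
        assert cfg.hr_cd8 == 1.0 and cfg.hr_m2 == 1.0

    def test_null_cohort_has_no_archetype_density_gap(self):
        cohort = simulate_null_cohort(replace(SMALL, n_cases=120), seed=3)
        exp = cohort.truth.expected_densities
        arch = cohort.truth.case_truth.set_index("case_id")["archetype"]
        cd8 = exp[exp.subclass == "CD8_sp"].groupby("case_id")["density"].mean()
        lo = np.log(cd8[arch == "desert"] + 1).mean()
        hi = np.log(cd8[arch == "inflamed"] + 1).mean()
        assert abs(hi - lo) < 0.5


class TestTreatment:
    def test_depletion_scales_expected_densities(self):
        cfg = replace(SMALL, n_per_group=40, depletion_factor=0.3,
                      recovery_factor=1.0)
        cohort = simulate_rectal_treatment(cfg, seed=4)
        exp = cohort.truth.expected_densities
        groups = cohort.truth.case_truth.set_index("case_id")["treatment_group"]
        m2 = exp[exp.subclass == "M2"].groupby("case_id")["density"].mean()
        naive = np.log(m2[groups == "naive"] + 1).mean()
        depleted = np.log(m2[groups == "RT_immediate"] + 1).mean()
        recovered = np.log(m2[groups == "RT_CRT_delayed"] + 1).mean()
        assert depleted < naive - 0.5
        assert abs(recovered - naive) < 0.5

    def test_stable_subclasses_unaffected(self):
        cfg = replace(SMALL, n_per_group=40, depletion_factor=0.3)
        cohort = simulate_rectal_treatment(cfg, seed=4)
        exp = cohort.truth.expected_densities
        groups = cohort.truth.case_truth.set_index("case_id")["treatment_group"]
        for sub in TREATMENT_STABLE_SUBCLASSES:
            d = exp[exp.subclass == sub].groupby("case_id")["density"].mean()
            naive = np.log(d[groups == "naive"] + 1).mean()
            depleted = np.log(d[groups == "RT_immediate"] + 1).mean()
            assert abs(naive - depleted) < 0.75

    def test_neutral_factors_make_groups_exchangeable(self):
        cfg = replace(SMALL, n_per_group=40, depletion_factor=1.0,
                      recovery_factor=1.0, m1_persistent_depletion=False)
        cohort = simulate_rectal_treatment(cfg, seed=4)
        exp = cohort.truth.expected_densities
        groups = cohort.truth.case_truth.set_index("case_id")["treatment_group"]
        m2 = exp[exp.subclass == "M2"].groupby("case_id")["density"].mean()
        means = np.log(m2 + 1).groupby(groups).mean()
        assert means.max() - means.min() < 0.6

    def test_all_cases_are_rectal(self):
        cohort = simulate_rectal_treatment(replace(SMALL, n_per_group=5), seed=2)
        assert (cohort.clinical["tumor_location"] == "rectum").all()


class TestSurvivalCohort:
    def test_event_fraction_near_target(self):
        df = simulate_survival_cohort(4000, hr=0.64, seed=10)
        assert 0.3 < df["event"].mean() < 0.5

    def test_high_group_lives_longer_when_protective(self):
        df = simulate_survival_cohort(4000, hr=0.5, seed=11)
        km_high = df.loc[df.high == 1, "time"].median()
        km_low = df.loc[df.high == 0, "time"].median()
        assert km_high > km_low
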