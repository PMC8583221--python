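import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss

from crcimmune.errors import DataError
from crcimmune.stats import (
    CohortData,
    analysis_recipes,
    bh_adjust,
    build_endpoints,
    chi_square,
    compose_endpoint,
    cox_fit,
    cox_per_subclass,
    mann_whitney,
    spearman_matrix,
    ward_cluster,
    wilcoxon_pratt,
)
import oracles


class TestSpearman:
    def test_monotone_and_antitone_pairs(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, 5.0]})
        df["b"] = df["a"] ** 2
        df["c"] = -df["a"]
        corr = spearman_matrix(df)
        assert corr.rho.loc["a", "b"] == pytest.approx(1.0)
        assert corr.rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        corr = spearman_matrix(df)
        for i in "abcde":
            for j in "abcde":
                r_oracle = np.corrcoef(
                    ss.rankdata(df[i]), ss.rankdata(df[j])
                )[0, 1]
                assert corr.rho.loc[i, j] == pytest.approx(r_oracle, abs=1e-12)

    def test_constant_column_flagged_undefined(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4.0], "b": [2, 2, 2, 2.0]})
        corr = spearman_matrix(df)
        assert np.isnan(corr.rho.loc["a", "b"])
        assert not corr.significant.loc["a", "b"]

    def test_pairwise_complete_uses_shared_cases(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, np.nan],
                           "b": [1, 2, 3, np.nan, 5.0]})
        corr = spearman_matrix(df)
        assert corr.rho.loc["a", "b"] == pytest.approx(1.0)


class TestWard:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(5, 0.1, (12, 3))])
        df = pd.DataFrame(X)
        res = ward_cluster(df, 2)
        labels = res.labels.to_numpy()
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]
        assert sorted(res.sizes.tolist()) == [10, 12]

    def test_k_equals_n_gives_singletons(self):
        df = pd.DataFrame(np.random.default_rng(1).normal(size=(6, 2)))
        res = ward_cluster(df, 6)
        assert res.labels.nunique() == 6

    def test_k_beyond_n_rejected(self):
        df = pd.DataFrame(np.eye(3))
        with pytest.raises(ValueError):
            ward_cluster(df, 4)

    def test_merge_heights_non_decreasing(self):
        df = pd.DataFrame(np.random.default_rng(2).normal(size=(20, 4)))
        res = ward_cluster(df, 2)
        heights = res.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_merge_sequence_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        X = rng.normal(size=(n, 3))
        res = ward_cluster(pd.DataFrame(X), 1)
        got = oracles.linkage_merge_sequence(res.linkage, n)
        expected = oracles.ward_merge_sequence(X)
        assert got == expected


class TestRankTests:
    def test_mann_whitney_exact_small_sample(self):
        u, p = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_u_statistics_sum_to_n1_n2(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=9), rng.normal(size=11)
        ux, _ = mann_whitney(x, y)
        uy, _ = mann_whitney(y, x)
        assert ux + uy == len(x) * len(y)

    def test_identical_samples_give_p_near_one(self):
        x = np.arange(30.0)
        _, p = mann_whitney(x, x, mode="asymptotic")
        assert p > 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_wilcoxon_pratt_all_positive_is_extreme(self):
        d = np.arange(1.0, 11.0)
        w, p = wilcoxon_pratt(d)
        assert w == d.size * (d.size + 1) / 2  # sum of all ranks
        assert p < 0.01

    def test_wilcoxon_pratt_symmetric_differences_null(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0, 4.0, -4.0])
        _, p = wilcoxon_pratt(d)
        assert p > 0.9

    def test_wilcoxon_pratt_zeros_shift_ranks(self):
        """Pratt: zeros occupy the lowest ranks before being dropped, so the
        positive-rank sum counts ranks 3,5,6 here (hand-ranked oracle)."""
        d = np.array([0.0, 0.0, 1.0, -2.0, 3.0, 4.0])
        w, _ = wilcoxon_pratt(d)
        assert w == 3 + 5 + 6
        # the zero-discarding variant ranks within {1,-2,3,4} only: W+ = 1+3+4
        nonzero = d[d != 0]
        w_discard = ss.rankdata(np.abs(nonzero))[nonzero > 0].sum()
        assert w_discard == 1 + 3 + 4
        assert w != w_discard

    def test_wilcoxon_all_zero_flagged(self):
        with pytest.raises(DataError):
            wilcoxon_pratt(np.zeros(5))


class TestBH:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_matches_stepup_oracle_and_order_invariance(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bh_adjust(p)
            np.testing.assert_allclose(q, oracles.bh_stepup(p), atol=1e-12)
            assert (q >= p - 1e-12).all()
            perm = rng.permutation(len(p))
            np.testing.assert_allclose(bh_adjust(p[perm]), q[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestChiSquare:
    def test_no_association_gives_zero_statistic(self):
        stat, p, _ = chi_square([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_matches_hand_pearson_formula(self):
        table = [[20, 5], [5, 20]]
        stat, _, _ = chi_square(table)
        assert stat == pytest.approx(oracles.pearson_chi2(table))

    def test_degrees_of_freedom_two_by_three(self):
        _, _, dof = chi_square([[5, 6, 7], [8, 9, 10]])
        assert dof == 2

    def test_zero_marginal_rejected(self):
        with pytest.raises(DataError):
            chi_square([[0, 0], [5, 5]])


class TestCox:
    def test_beta_matches_partial_likelihood_grid_search(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        group = [0.0, 1.0, 0.0, 1.0]
        df = pd.DataFrame({"time": times, "event": events, "x": group})
        est = cox_fit(df)[0]
        beta_oracle = oracles.cox_grid_mle(times, events, group)
        assert np.log(est.hr) == pytest.approx(beta_oracle, abs=1e-3)

    def test_constant_covariate_reports_unit_hazard(self):
        df = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 0, 1],
                           "x": [0.0, 0, 0, 0]})
        est = cox_fit(df)[0]
        assert est.hr == 1.0 and est.p == 1.0

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(DataError):
            cox_fit(df)

    def test_ci_contains_hr_and_q_at_least_p(self, small_result, small_cohort):
        ep = build_endpoints(small_cohort.clinical, "OS")
        out = cox_per_subclass(small_result.scores, ep, coding="dichotomized")
        fitted = out.dropna(subset=["p"])
        assert ((fitted.ci_low <= fitted.hr) & (fitted.hr <= fitted.ci_high)).all()
        assert (fitted.q >= fitted.p - 1e-12).all()
        assert (fitted.hr > 0).all()


class TestEndpoints:
    def test_composite_rfs_takes_earliest_event(self):
        idx = ["a", "b", "c"]
        rec = pd.Series([200.0, np.nan, np.nan], index=idx)
        death = pd.Series([400.0, np.nan, 600.0], index=idx)
        fup = pd.Series([1000.0, 1000.0, 1000.0], index=idx)
        out = compose_endpoint(rec, death, fup)
        # death after recurrence -> RFS at recurrence
        assert out.loc["a"].tolist() == [200.0, 1]
        # alive, no recurrence -> censored at follow-up
        assert out.loc["b"].tolist() == [1000.0, 0]
        # death without recurrence still counts as RFS event
        assert out.loc["c"].tolist() == [600.0, 1]

    def test_build_endpoints_consistency(self, small_cohort):
        os_ep = build_endpoints(small_cohort.clinical, "OS")
        rfs_ep = build_endpoints(small_cohort.clinical, "RFS")
        joined = os_ep.join(rfs_ep, lsuffix="_os", rsuffix="_rfs")
        assert (joined["time_rfs"] <= joined["time_os"] + 1e-9).all()
        assert os_ep["event"].isin([0, 1]).all()


class TestRecipes:
    def test_missing_stage_four_recipe_skipped_with_log(self, small_result,
                                                        small_cohort):
        clin = small_cohort.clinical.copy()
        clin = clin[clin["stage"] != "IV"]
        scores = small_result.scores
        bundle = analysis_recipes(CohortData(clinical=clin, scores=scores),
                                  coding="dichotomized")
        assert bundle.stage4_os is None
        assert any("stage4" in s for s in bundle.skipped)

    def test_full_cohort_produces_survival_families(self, small_result,
                                                    small_cohort):
        labels = small_result.cluster.labels
        bundle = analysis_recipes(
            CohortData(clinical=small_cohort.clinical,
                       scores=small_result.scores,
                       cluster_labels=labels),
            coding="dichotomized",
        )
        assert bundle.os_univariable is not None
        assert len(bundle.os_univariable) == 15
        assert bundle.rfs_multivariable is not None
        assert bundle.enrichment is not None
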