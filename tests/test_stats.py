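"""Clustered inference: annual progression, GEE vs OLS/statsmodels
oracles, BH-FDR step-up, exact Wilcoxon enumeration, cohort descriptives."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from oculovasc.stats import (
    annual_progression,
    bh_fdr,
    cohort_table,
    fit_models,
    gee_fit,
    wilcoxon_rank_sum,
)
from oculovasc.synth import CohortParams, gen_cohort


class TestAnnualProgression:
    @pytest.mark.parametrize("dx,visit,years,expect", [
        (2.0, 2.0, 5.0, 0.0),
        (2.0, 4.0, 4.0, 0.5),
        (3.0, 2.0, 2.0, -0.5),  # improvement allowed
    ])
    def test_arithmetic(self, dx, visit, years, expect):
        assert annual_progression(dx, visit, years) == expect

    def test_nonpositive_years_rejected(self):
        with pytest.raises(ValueError):
            annual_progression(1.0, 2.0, 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(0, 10), st.floats(0, 10), st.floats(0.5, 40))
    def test_antisymmetric_under_swap(self, a, b, years):
        assert annual_progression(a, b, years) == pytest.approx(
            -annual_progression(b, a, years), abs=1e-12)


class TestGee:
    def test_singleton_clusters_equal_ols(self):
        p = CohortParams(n_ctrl=40, n_msnon=30, n_mson=20, eyes_per_subject=1,
                         rho=0.0, seed=9, outcome_means={"Y": 50},
                         outcome_sds={"Y": 5},
                         effect_sizes={"Y": {"MSnON": -3, "MSON": 2}},
                         covariate_effects={"Y": {"age": 0.1}})
        df, _ = gen_cohort(p)
        fit = gee_fit(df, "Y", ["group", "age"], reference={"group": "Ctrl"})
        X = np.column_stack([
            np.ones(len(df)),
            (df.group == "MSON").astype(float),
            (df.group == "MSnON").astype(float),
            df.age,
        ])
        ols = np.linalg.lstsq(X, df.Y.to_numpy(), rcond=None)[0]
        ours = fit.params[["Intercept", "group[MSON]", "group[MSnON]", "age"]].to_numpy()
        assert np.max(np.abs((ours - ols) / ols)) < 1e-6

    def test_matches_statsmodels_on_clustered_data(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        sm = pytest.importorskip("statsmodels.api")
        p = CohortParams(n_ctrl=60, n_msnon=40, n_mson=0, rho=0.5, seed=3,
                         outcome_means={"Y": 50}, outcome_sds={"Y": 5},
                         effect_sizes={"Y": {"MSnON": -3}})
        df, _ = gen_cohort(p)
        ours = gee_fit(df, "Y", ["group"], reference={"group": "Ctrl"})
        ref = smf.gee('Y ~ C(group, Treatment("Ctrl"))', groups="subject_id",
                      data=df, cov_struct=sm.cov_struct.Exchangeable()).fit()
        assert ours.params["group[MSnON]"] == pytest.approx(ref.params.iloc[1], rel=1e-5)
        assert ours.robust_se["group[MSnON]"] == pytest.approx(ref.bse.iloc[1], rel=1e-4)
        assert ours.rho_hat == pytest.approx(ref.cov_struct.dep_params, abs=1e-3)

    def test_effect_and_rho_recovered_over_repeats(self):
        betas, rhos = [], []
        for s in range(30):
            p = CohortParams(n_ctrl=100, n_msnon=100, n_mson=0, rho=0.6,
                             seed=500 + s, outcome_means={"Y": 50},
                             outcome_sds={"Y": 5},
                             effect_sizes={"Y": {"MSnON": -3.0}})
            df, _ = gen_cohort(p)
            fit = gee_fit(df, "Y", ["group"], reference={"group": "Ctrl"})
            betas.append(fit.params["group[MSnON]"])
            rhos.append(fit.rho_hat)
        assert np.mean(betas) == pytest.approx(-3.0, abs=0.3)
        assert np.mean(rhos) == pytest.approx(0.6, abs=0.05)

    def test_zero_outcome_gives_zero_betas(self):
        p = CohortParams(n_ctrl=10, n_msnon=5, n_mson=0, seed=1)
        df, _ = gen_cohort(p)
        df["Z"] = 0.0
        fit = gee_fit(df, "Z", ["group"], reference={"group": "Ctrl"})
        assert np.allclose(fit.params.to_numpy(), 0.0)

    def test_ci_is_beta_plus_minus_1p96_se(self):
        p = CohortParams(seed=4, outcome_means={"Y": 10}, outcome_sds={"Y": 2})
        df, _ = gen_cohort(p)
        fit = gee_fit(df, "Y", ["group"], reference={"group": "Ctrl"})
        assert np.allclose(fit.ci_lo, fit.params - 1.96 * fit.robust_se)
        assert np.allclose(fit.ci_hi, fit.params + 1.96 * fit.robust_se)

    def test_rank_deficiency_names_columns(self):
        p = CohortParams(seed=2, outcome_means={"Y": 1}, outcome_sds={"Y": 1})
        df, _ = gen_cohort(p)
        df["age_copy"] = df["age"]
        with pytest.raises(ValueError, match="age_copy"):
            gee_fit(df, "Y", ["age", "age_copy"])


class TestBhFdr:
    @staticmethod
    def brute_force(p):
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        for rank_i, idx in enumerate(order, start=1):
            candidates = [p[order[j - 1]] * m / j
                          for j in range(rank_i, m + 1)]
            adj[idx] = min(1.0, min(candidates))
        return adj

    def test_hand_worked_example(self):
        adj, rej = bh_fdr([0.01, 0.04, 0.03, 0.005])
        assert np.allclose(adj, [0.02, 0.04, 0.04, 0.02])
        assert rej.all()

    def test_constant_case(self):
        adj, _ = bh_fdr([0.01] * 10)
        assert np.allclose(adj, 0.01)

    def test_single_p_unchanged(self):
        adj, _ = bh_fdr([0.2])
        assert adj[0] == 0.2

    def test_empty_input(self):
        adj, rej = bh_fdr([])
        assert adj.size == 0 and rej.size == 0

    @settings(max_examples=250, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, p):
        adj, _ = bh_fdr(p)
        assert np.allclose(adj, self.brute_force(p))


class TestWilcoxon:
    @staticmethod
    def enumeration_p(x, y):
        """Full enumeration over all labelings of the combined sample."""
        combined = np.concatenate([x, y])
        n, total = len(x), len(combined)
        ranks = sps.rankdata(combined)
        w_obs = ranks[:n].sum()
        sums = [ranks[list(idx)].sum()
                for idx in itertools.combinations(range(total), n)]
        sums = np.asarray(sums)
        p_le = np.mean(sums <= w_obs + 1e-9)
        p_ge = np.mean(sums >= w_obs - 1e-9)
        return min(1.0, 2 * min(p_le, p_ge))

    def test_small_sample_exact(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(1 / 3)

    def test_extreme_shift_exact(self):
        res = wilcoxon_rank_sum([11, 12, 13, 14, 15], [1, 2, 3, 4, 5])
        assert res["p"] == pytest.approx(2 / math.comb(10, 5))

    def test_identical_samples_degenerate(self):
        res = wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0])
        assert res["p"] == 1.0 and res["degenerate"]

    @settings(max_examples=120, derandomize=True)
    @given(st.integers(1, 6), st.integers(1, 6), st.randoms(use_true_random=False))
    def test_exact_p_equals_full_enumeration(self, n, m, rnd):
        if n + m > 12:
            n = min(n, 12 - m)
        vals = rnd.sample(range(1000), n + m)  # distinct -> no ties
        x, y = np.array(vals[:n], float), np.array(vals[n:], float)
        res = wilcoxon_rank_sum(x, y)
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(self.enumeration_p(x, y), abs=1e-12)

    def test_large_or_tied_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 30), rng.normal(0.8, 1, 30)
        res = wilcoxon_rank_sum(x, y)
        assert res["method"] == "normal-approx"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided")
        assert res["p"] == pytest.approx(ref.pvalue, rel=0.02)
        res_t = wilcoxon_rank_sum([1, 2, 2, 3], [2, 4, 4, 5])
        assert res_t["method"] == "normal-approx-ties"


class TestCohortTable:
    def test_order_statistics(self):
        df = pd.DataFrame({"group": ["A"] * 5 + ["B"] * 5,
                           "v": [1, 2, 3, 4, 5, 2, 3, 4, 5, 6]})
        tab = cohort_table(df, continuous=["v"])
        row = tab[(tab.group == "A") & (tab.statistic == "Median (IQR)")]
        assert row.value.iloc[0] == "3.00 (2.00, 4.00)"

    def test_constant_variable_zero_spread(self):
        df = pd.DataFrame({"group": ["A"] * 4 + ["B"] * 4, "v": [7.0] * 8})
        tab = cohort_table(df, continuous=["v"])
        assert "(0.00)" in tab[tab.statistic == "Mean (SD)"].value.iloc[0]

    def test_fisher_exact_on_sparse_2x2(self):
        # 2x2 table {{8,2},{1,9}}: Fisher two-sided p ~ 0.0055
        g = ["A"] * 10 + ["B"] * 10
        v = ["yes"] * 8 + ["no"] * 2 + ["yes"] * 1 + ["no"] * 9
        tab = cohort_table(pd.DataFrame({"group": g, "flag": v}), categorical=["flag"])
        assert tab.test.iloc[0] == "fisher-exact"
        assert tab.p.iloc[0] == pytest.approx(0.0055, abs=5e-4)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            cohort_table(pd.DataFrame())


class TestModelPresets:
    def test_group_models_produce_fdr_per_family(self):
        p = CohortParams(seed=6, outcome_means={"Y1": 10, "Y2": 20},
                         outcome_sds={"Y1": 2, "Y2": 3},
                         effect_sizes={"Y1": {"MSnON": -2, "MSON": -2}})
        df, _ = gen_cohort(p)
        res = fit_models(df, ["Y1", "Y2"], preset="group_unadjusted")
        exp = res[res.term.str.startswith("group")]
        assert exp.p_fdr.notna().all()
        assert (exp.p_fdr >= exp.p - 1e-12).all()

    def test_adjusted_model_includes_covariates(self):
        p = CohortParams(seed=8, outcome_means={"Y": 10}, outcome_sds={"Y": 2})
        df, _ = gen_cohort(p)
        res = fit_models(df, ["Y"], preset="group_adjusted")
        assert {"iop", "hypertension"} <= set(res.term)

    def test_disability_preset_restricted_to_msnon(self):
        p = CohortParams(seed=5, n_msnon=20, outcome_means={"Y": 10},
                         outcome_sds={"Y": 2})
        df, _ = gen_cohort(p)
        res = fit_models(df, ["Y"], preset="edss")
        assert res.n_eyes.iloc[0] == 40  # 20 MSnON subjects, both eyes
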