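"""Cohort statistics vs independent oracles (normal equations, enumeration)."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from venasl.stats import (
    consensus_rating,
    corr_matrix,
    descriptive_table,
    ols,
    pairwise_adjusted,
    rating_agreement,
    stepwise_ols,
)
from venasl.synthetic import HEMODYNAMIC_VARIABLES, CohortGenParams, simulate_cohort


def _normal_equations(y, X):
    """Closed-form OLS oracle: beta = (X'X)^-1 X'y with analytic SEs."""
    Xm = np.column_stack([np.ones(len(y)), X])
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    beta = xtx_inv @ Xm.T @ y
    resid = y - Xm @ beta
    df = len(y) - Xm.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se


class TestOls:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = ols(2 * x + 1, pd.DataFrame({"x": x}))
        assert res.estimates == pytest.approx([1.0, 2.0])
        assert res.r2 == pytest.approx(1.0)

    def test_orthogonal_predictor_zero_slope(self):
        x = np.array([-1.0, 1.0, -1.0, 1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        res = ols(y, pd.DataFrame({"x": x}))
        assert res.estimates[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((50, 3))
        y = X @ [1.5, -2.0, 0.3] + rng.standard_normal(50)
        res = ols(y, pd.DataFrame(X, columns=list("abc")))
        beta, se = _normal_equations(y, X)
        assert np.allclose(res.estimates, beta, atol=1e-8)
        assert np.allclose(res.std_errors, se, atol=1e-8)

    def test_rank_deficiency_names_collinear_terms(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            ols(rng.standard_normal(30), X)

    def test_more_terms_than_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            ols(rng.standard_normal(3), pd.DataFrame(rng.standard_normal((3, 3))))


class TestCorrMatrix:
    def test_family_size_for_13_variables(self):
        cohort, _ = simulate_cohort(CohortGenParams(seed=0))
        cm = corr_matrix(cohort, HEMODYNAMIC_VARIABLES)
        assert len(cm.variables) == 13
        assert cm.n_tests == 78
        off = ~np.eye(13, dtype=bool)
        expected = np.minimum(cm.p.to_numpy()[off] * 78, 1.0)
        assert np.allclose(cm.p_bonferroni.to_numpy()[off], expected)

    def test_perfect_correlation(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0)})
        cm = corr_matrix(df, ["x", "y"])
        assert cm.r.loc["x", "y"] == pytest.approx(1.0)
        assert cm.p.loc["x", "y"] < 1e-10

    def test_r_matches_direct_covariance_formula(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([2.0, 3.0, 9.0, 1.0, 4.0])
        cm = corr_matrix(pd.DataFrame({"x": x, "y": y}), ["x", "y"])
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert cm.r.loc["x", "y"] == pytest.approx(num / den, abs=1e-12)

    def test_r_squared_equals_univariate_ols_r2(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        df = pd.DataFrame({"x": x, "y": y})
        cm = corr_matrix(df, ["x", "y"])
        res = ols(df["y"], df[["x"]])
        assert cm.r.loc["x", "y"] ** 2 == pytest.approx(res.r2, abs=1e-10)

    def test_zero_variance_flagged_nan(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        cm = corr_matrix(df, ["x", "y"])
        assert np.isnan(cm.r.loc["x", "y"])


class TestPairwiseAdjusted:
    def test_entry_equals_direct_two_covariate_model(self):
        cohort, _ = simulate_cohort(CohortGenParams(n_subjects=60, seed=5))
        variables = ["vhs", "cbf", "do2"]
        mat = pairwise_adjusted(cohort, "oef", variables)
        direct = ols(cohort["oef"], cohort[["vhs", "cbf"]])
        assert mat.loc["vhs", "cbf"] == pytest.approx(direct.p_values[1], abs=1e-12)

    def test_diagonal_is_univariate_p(self):
        cohort, _ = simulate_cohort(CohortGenParams(n_subjects=60, seed=5))
        mat = pairwise_adjusted(cohort, "oef", ["vhs", "cbf"])
        uni = ols(cohort["oef"], cohort[["vhs"]])
        assert mat.loc["vhs", "vhs"] == pytest.approx(uni.p_values[1], abs=1e-12)

    def test_pure_noise_covariate_leaves_p_nearly_unchanged(self):
        rng = np.random.default_rng(11)
        n = 10_000
        x = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        y = 0.1 * x + rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x": x, "noise": noise})
        mat = pairwise_adjusted(df, "y", ["x", "noise"])
        # on the z scale the adjusted and univariate tests nearly coincide
        from scipy.stats import norm

        z_adj = norm.isf(mat.loc["x", "noise"] / 2)
        z_uni = norm.isf(mat.loc["x", "x"] / 2)
        assert z_adj == pytest.approx(z_uni, rel=0.05)

    def test_duplicated_variable_raises_rank_error(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.standard_normal(30)})
        df["a"] = rng.standard_normal(30)
        df["b"] = df["a"]
        with pytest.raises(ValueError, match="collinear"):
            pairwise_adjusted(df, "y", ["a", "b"])


class TestStepwise:
    def test_single_true_predictor_selected_exactly(self):
        rng = np.random.default_rng(42)
        X = pd.DataFrame(
            rng.standard_normal((200, 6)), columns=[f"x{i}" for i in range(6)]
        )
        y = X["x0"] + rng.normal(0, 0.1, 200)
        res, trace = stepwise_ols(y, X)
        assert res.terms == ["Intercept", "x0"]
        assert trace[0].action == "add" and trace[0].term == "x0"

    def test_constant_outcome_gives_intercept_only(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=list("abc"))
        res, trace = stepwise_ols(np.full(50, 2.5), X)
        assert res.terms == ["Intercept"]
        assert trace == []

    def test_permissive_thresholds_build_full_model(self, rng):
        X = pd.DataFrame(rng.standard_normal((80, 4)), columns=list("abcd"))
        y = rng.standard_normal(80)
        res, trace = stepwise_ols(y, X, p_enter=1.0, p_remove=1.0)
        assert sorted(res.terms[1:]) == list("abcd")
        assert all(t.action == "add" for t in trace)

    def test_null_inclusion_rate_consistent_with_p_enter(self):
        """With k independent noise candidates, the family-wise probability
        of admitting at least one is ~ 1 - (1 - p_enter)^k."""
        k, reps, hits = 5, 400, 0
        for rep in range(reps):
            r = np.random.default_rng(60_000 + rep)
            X = pd.DataFrame(
                r.standard_normal((200, k)), columns=[f"x{i}" for i in range(k)]
            )
            res, _ = stepwise_ols(pd.Series(r.standard_normal(200)), X)
            hits += len(res.terms) > 1
        expected = 1 - 0.95**k
        assert abs(hits / reps - expected) < 0.06  # 3 MC sigmas ~ 0.063

    def test_tie_breaking_by_candidate_order(self):
        # two identical-strength candidates: the first in column order enters
        rng = np.random.default_rng(9)
        x = rng.standard_normal(100)
        X = pd.DataFrame({"first": x, "second": x.copy()})
        y = x + rng.normal(0, 0.5, 100)
        res, trace = stepwise_ols(y, X)
        assert trace[0].term == "first"


class TestDescriptiveTable:
    def test_identical_groups_null_pvalues(self):
        df = pd.DataFrame(
            {
                "v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                "grp": [0, 0, 0, 1, 1, 1],
                "sex": ["F", "M", "F", "F", "M", "F"],
            }
        )
        out = descriptive_table(
            df, ["v"], group_col="grp", group_rule=lambda s: s > 0,
            sex_col="sex", race_col=None,
        )
        v_row = out[out["variable"] == "v"].iloc[0]
        assert v_row["p_value"] == pytest.approx(1.0)
        sex_row = out[out["variable"] == "sex"].iloc[0]
        assert sex_row["p_value"] == pytest.approx(1.0)

    def test_fisher_exact_matches_hypergeometric_enumeration(self):
        # 2x2 table a=5, b=0, c=0, d=5: two-sided p by direct enumeration
        df = pd.DataFrame(
            {
                "grp": [1] * 5 + [0] * 5,
                "sex": ["F"] * 5 + ["M"] * 5,
            }
        )
        out = descriptive_table(
            df, [], group_col="grp", group_rule=lambda s: s > 0,
            sex_col="sex", race_col=None,
        )
        p_fisher = out[out["variable"] == "sex"].iloc[0]["p_value"]
        # enumeration oracle: P(table at least as extreme) over the
        # hypergeometric distribution with margins (5,5) x (5,5)
        total = comb(10, 5)
        probs = np.array([comb(5, k) * comb(5, 5 - k) / total for k in range(6)])
        p_enum = probs[probs <= probs[5] + 1e-12].sum()
        assert p_fisher == pytest.approx(p_enum, abs=1e-12)

    def test_normality_gate_switches_test(self):
        rng = np.random.default_rng(8)
        normal_var = rng.standard_normal(60)
        skewed_var = rng.lognormal(0, 1.5, 60)
        df = pd.DataFrame(
            {"normal": normal_var, "skewed": skewed_var, "grp": rng.integers(0, 2, 60)}
        )
        out = descriptive_table(
            df, ["normal", "skewed"], group_col="grp",
            group_rule=lambda s: s > 0, sex_col=None, race_col=None,
        )
        assert out[out["variable"] == "normal"].iloc[0]["test"] == "welch_t"
        assert out[out["variable"] == "skewed"].iloc[0]["test"] == "mann_whitney"

    def test_tiny_group_reports_undefined(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0], "grp": [0, 0, 0, 1]})
        out = descriptive_table(
            df, ["v"], group_col="grp", group_rule=lambda s: s > 0,
            sex_col=None, race_col=None,
        )
        assert out.iloc[0]["test"] == "undefined"
        assert np.isnan(out.iloc[0]["p_value"])


class TestRatingAgreement:
    def test_identical_ratings(self):
        tau, _ = rating_agreement([0, 1, 2, 1, 0, 2], [0, 1, 2, 1, 0, 2])
        assert tau == pytest.approx(1.0)

    def test_exact_reversal_without_ties(self):
        tau, _ = rating_agreement([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert tau == pytest.approx(-1.0)

    def test_matches_pair_enumeration_oracle(self):
        a = np.array([0, 1, 2, 1, 0, 2])
        b = np.array([1, 1, 2, 0, 0, 2])
        tau, _ = rating_agreement(a, b)
        # O(n^2) concordant/discordant enumeration with tie correction
        n = len(a)
        conc = disc = ties_a = ties_b = 0
        for i in range(n):
            for j in range(i + 1, n):
                da, db = a[i] - a[j], b[i] - b[j]
                if da == 0 and db == 0:
                    continue
                if da == 0:
                    ties_a += 1
                elif db == 0:
                    ties_b += 1
                elif da * db > 0:
                    conc += 1
                else:
                    disc += 1
        n0 = n * (n - 1) / 2
        denom = np.sqrt((n0 - _tie_term(a)) * (n0 - _tie_term(b)))
        assert tau == pytest.approx((conc - disc) / denom, abs=1e-12)

    def test_constant_ratings_undefined(self):
        tau, p = rating_agreement([1, 1, 1, 1], [0, 1, 2, 1])
        assert np.isnan(tau) and np.isnan(p)

    def test_consensus_mode_and_tie_flag(self):
        ratings = np.array(
            [
                [0, 0, 0, 1],  # mode 0
                [2, 2, 1, 2],  # mode 2
                [0, 0, 1, 1],  # 2-2 tie -> flag, smaller value
            ]
        )
        modes, ties = consensus_rating(ratings)
        assert list(modes) == [0, 2, 0]
        assert list(ties) == [False, False, True]


def _tie_term(x):
    vals, counts = np.unique(x, return_counts=True)
    return sum(c * (c - 1) / 2 for c in counts)
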