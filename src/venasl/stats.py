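"""Cohort statistics: descriptives, correlations, regressions, agreement.

Implements the analysis battery applied to the subject table: grouped
descriptive comparisons (Welch's t or Mann-Whitney U gated by a Shapiro-Wilk
normality test, Fisher's exact test for sex, chi-square for race), a Pearson
correlation matrix with a Bonferroni family of p*(p-1)/2 tests, ordinary
least squares with full inference, pairwise-adjusted two-covariate models of
OEF, a MATLAB-stepwiselm-style stepwise regression (F-test on the change in
residual sum of squares, p-enter 0.05 / p-remove 0.10, linear terms only),
and Kendall tau-b agreement between ordinal rating series.

Missing data: correlations are pairwise-complete; regressions are listwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "CorrelationMatrix",
    "StepwiseTrace",
    "descriptive_table",
    "corr_matrix",
    "ols",
    "pairwise_adjusted",
    "stepwise_ols",
    "rating_agreement",
    "consensus_rating",
]


@dataclass
class RegressionResult:
    """OLS fit summary: per-term estimates with t-based inference."""

    terms: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    r2: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "std_error": self.std_errors,
                "t_stat": self.t_stats,
                "p_value": self.p_values,
            }
        )


@dataclass
class CorrelationMatrix:
    """Pearson r/p matrices with Bonferroni-corrected companions."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    p_bonferroni: pd.DataFrame
    n_tests: int


@dataclass
class StepwiseTrace:
    """One selection event: step index, action, term, and the decisive p."""

    step: int
    action: str  # "add" or "remove"
    term: str
    p_value: float


def _as_2d(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def ols(y, X, add_intercept: bool = True) -> RegressionResult:
    """Ordinary least squares with intercept and two-sided t inference.

    Raises on rank deficiency, naming the collinear columns instead of
    silently falling back to a pseudo-inverse.
    """
    Xm, names = _as_2d(X)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y) & np.all(np.isfinite(Xm), axis=1)
    y, Xm = y[keep], Xm[keep]
    if add_intercept:
        Xm = np.column_stack([np.ones(len(y)), Xm])
        names = ["Intercept"] + names
    n, k = Xm.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than terms ({k})")
    rank = np.linalg.matrix_rank(Xm)
    if rank < k:
        # identify offending columns via QR pivoting on the correlation pattern
        bad = []
        for j in range(k):
            others = np.delete(Xm, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    fit = sm.OLS(y, Xm).fit()
    return RegressionResult(
        terms=names,
        estimates=np.asarray(fit.params),
        std_errors=np.asarray(fit.bse),
        t_stats=np.asarray(fit.tvalues),
        p_values=np.asarray(fit.pvalues),
        r2=float(fit.rsquared),
        n=n,
    )


def corr_matrix(
    cohort: pd.DataFrame, variables: list[str] | tuple[str, ...]
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with Bonferroni correction.

    The family size is p*(p-1)/2 over the p requested variables; corrected
    p-values are min(1, p_raw * n_tests).  Zero-variance variables yield
    NaN entries (flagged, not errored).
    """
    variables = list(variables)
    p_vars = len(variables)
    n_tests = p_vars * (p_vars - 1) // 2
    r = pd.DataFrame(np.eye(p_vars), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((p_vars, p_vars)), index=variables, columns=variables)
    for i in range(p_vars):
        for j in range(i + 1, p_vars):
            a = cohort[variables[i]].to_numpy(dtype=float)
            b = cohort[variables[j]].to_numpy(dtype=float)
            keep = np.isfinite(a) & np.isfinite(b)
            a, b = a[keep], b[keep]
            if len(a) < 3 or a.std() == 0 or b.std() == 0:
                rij, pij = np.nan, np.nan
            else:
                res = sps.pearsonr(a, b)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    p_bonf = (p * n_tests).clip(upper=1.0)
    np.fill_diagonal(p_bonf.values, 0.0)
    return CorrelationMatrix(
        variables=variables, r=r, p=p, p_bonferroni=p_bonf, n_tests=n_tests
    )


def pairwise_adjusted(
    cohort: pd.DataFrame, outcome: str, variables: list[str] | tuple[str, ...]
) -> pd.DataFrame:
    """Adjusted p-value matrix from two-covariate models of the outcome.

    Entry (i, j) is the p-value of variable i in the model
    outcome ~ 1 + var_i + var_j; the diagonal holds the univariate p-value.
    """
    variables = list(variables)
    out = pd.DataFrame(
        np.full((len(variables), len(variables)), np.nan),
        index=variables,
        columns=variables,
    )
    y = cohort[outcome]
    for i, vi in enumerate(variables):
        res_uni = ols(y, cohort[[vi]])
        out.iloc[i, i] = res_uni.p_values[1]
        for j, vj in enumerate(variables):
            if i == j:
                continue
            res = ols(y, cohort[[vi, vj]])
            out.iloc[i, j] = res.p_values[1]
    return out


def _sse(y: np.ndarray, Xm: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    resid = y - Xm @ beta
    return float(resid @ resid)


def stepwise_ols(
    y,
    candidates: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> tuple[RegressionResult, list[StepwiseTrace]]:
    """Stepwise linear regression with F-tests on the residual sum of squares.

    Starting from an intercept-only model, repeatedly add the candidate with
    the smallest partial F-test p-value below ``p_enter``; after each
    addition, remove any included term whose F-test p-value exceeds
    ``p_remove`` (worst first), until a fixed point.  Ties break by the
    candidate column order.  Degrees of freedom are guarded: a candidate is
    only considered while n > current terms + 2.  Returns the final model
    (intercept-only if nothing enters) and the full selection trace.
    """
    names = list(candidates.columns)
    y_full = np.asarray(y, dtype=float)
    X_full = candidates.to_numpy(dtype=float)
    keep = np.isfinite(y_full) & np.all(np.isfinite(X_full), axis=1)
    y_arr, X_all = y_full[keep], X_full[keep]
    n = len(y_arr)

    included: list[str] = []
    trace: list[StepwiseTrace] = []
    step = 0

    def design(terms: list[str]) -> np.ndarray:
        cols = [np.ones(n)] + [X_all[:, names.index(t)] for t in terms]
        return np.column_stack(cols)

    centered = y_arr - y_arr.mean() if n else y_arr
    sse_floor = 1e-12 * max(float(centered @ centered), np.finfo(float).tiny)

    def f_test_p(sse_small: float, sse_big: float, df_big: int) -> float:
        if sse_small <= sse_floor:
            return 1.0  # already a perfect fit; nothing left to explain
        if sse_big <= 0:
            return 0.0
        f = (sse_small - sse_big) / (sse_big / df_big)
        if f < 0:
            return 1.0
        return float(sps.f.sf(f, 1, df_big))

    while True:
        changed = False
        # forward step
        sse_cur = _sse(y_arr, design(included))
        best_p, best_term = None, None
        for term in names:
            if term in included or n <= len(included) + 3:
                continue
            Xc = design(included + [term])
            if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
                continue  # collinear with current model; cannot enter
            p_val = f_test_p(sse_cur, _sse(y_arr, Xc), n - Xc.shape[1])
            if p_val < p_enter and (best_p is None or p_val < best_p):
                best_p, best_term = p_val, term
        if best_term is not None:
            included.append(best_term)
            step += 1
            trace.append(StepwiseTrace(step, "add", best_term, best_p))
            changed = True

        # backward steps until stable
        while included:
            Xc = design(included)
            sse_big = _sse(y_arr, Xc)
            df_big = n - Xc.shape[1]
            worst_p, worst_term = None, None
            for term in included:
                reduced = [t for t in included if t != term]
                p_val = f_test_p(_sse(y_arr, design(reduced)), sse_big, df_big)
                if p_val > p_remove and (worst_p is None or p_val > worst_p):
                    worst_p, worst_term = p_val, term
            if worst_term is None:
                break
            included.remove(worst_term)
            step += 1
            trace.append(StepwiseTrace(step, "remove", worst_term, worst_p))
            changed = True

        if not changed:
            break

    if included:
        result = ols(pd.Series(y_arr), pd.DataFrame(
            {t: X_all[:, names.index(t)] for t in included}
        ))
    else:
        # intercept-only summary
        mean = float(y_arr.mean())
        se = float(y_arr.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        tstat = mean / se if se and se > 0 else np.nan
        p_val = 2 * sps.t.sf(abs(tstat), n - 1) if np.isfinite(tstat) else np.nan
        result = RegressionResult(
            terms=["Intercept"],
            estimates=np.array([mean]),
            std_errors=np.array([se]),
            t_stats=np.array([tstat]),
            p_values=np.array([p_val]),
            r2=0.0,
            n=n,
        )
    return result, trace


_CONTINUOUS_TESTS = ("welch_t", "mann_whitney")


def descriptive_table(
    cohort: pd.DataFrame,
    continuous: list[str],
    group_col: str = "vhs_rating",
    group_rule=lambda s: s > 0,
    sex_col: str | None = "sex",
    race_col: str | None = "race",
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Grouped descriptive summary with automatic test selection.

    Continuous variables are summarized as mean +/- SD per group and
    compared with Welch's t-test when the pooled variable passes a
    Shapiro-Wilk normality test at ``normality_alpha``, otherwise with the
    Mann-Whitney U test.  Sex uses Fisher's exact test on the 2x2 table,
    race a chi-square test.  A Bonferroni flag marks rows significant after
    correcting for the number of tested rows.  Groups with fewer than two
    subjects yield undefined (NaN) test results.
    """
    grp = group_rule(cohort[group_col]).astype(bool)
    g1, g0 = cohort[grp], cohort[~grp]
    rows = []
    for var in continuous:
        a = g1[var].dropna().to_numpy(dtype=float)
        b = g0[var].dropna().to_numpy(dtype=float)
        pooled = np.concatenate([a, b])
        row = {
            "variable": var,
            "mean_total": pooled.mean() if len(pooled) else np.nan,
            "sd_total": pooled.std(ddof=1) if len(pooled) > 1 else np.nan,
            "mean_group1": a.mean() if len(a) else np.nan,
            "sd_group1": a.std(ddof=1) if len(a) > 1 else np.nan,
            "mean_group0": b.mean() if len(b) else np.nan,
            "sd_group0": b.std(ddof=1) if len(b) > 1 else np.nan,
        }
        if len(a) < 2 or len(b) < 2:
            row.update(test="undefined", p_value=np.nan)
        else:
            normal = bool(sps.shapiro(pooled).pvalue > normality_alpha)
            if np.ptp(pooled) == 0:
                # degenerate: identical values everywhere -> no group difference
                row.update(test="welch_t", p_value=1.0)
            elif normal:
                res = sps.ttest_ind(a, b, equal_var=False)
                row.update(test="welch_t", p_value=float(res.pvalue))
            else:
                res = sps.mannwhitneyu(a, b, alternative="two-sided")
                row.update(test="mann_whitney", p_value=float(res.pvalue))
        rows.append(row)

    if sex_col is not None:
        tab = pd.crosstab(cohort[sex_col], grp)
        if tab.shape == (2, 2):
            _, p_val = sps.fisher_exact(tab.to_numpy())
        else:
            p_val = np.nan
        rows.append({"variable": sex_col, "test": "fisher_exact", "p_value": p_val})
    if race_col is not None:
        tab = pd.crosstab(cohort[race_col], grp)
        try:
            p_val = float(sps.chi2_contingency(tab.to_numpy()).pvalue)
        except ValueError:
            p_val = np.nan
        rows.append({"variable": race_col, "test": "chi2", "p_value": p_val})

    out = pd.DataFrame(rows)
    n_tested = int(out["p_value"].notna().sum())
    out["n_tests_bonferroni"] = n_tested
    out["significant_bonferroni"] = out["p_value"] * n_tested < 0.05
    return out


def rating_agreement(ratings_a, ratings_b) -> tuple[float, float]:
    """Kendall tau-b (tie-corrected) between two ordinal rating series."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("rating series must be equal length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan, np.nan  # degenerate: agreement undefined for constant ratings
    res = sps.kendalltau(a, b, variant="b")
    return float(res.statistic), float(res.pvalue)


def consensus_rating(ratings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject mode of repeated ordinal ratings, flagging unresolved ties.

    ``ratings`` is (n_subjects, n_ratings).  Returns ``(mode, tie_flag)``;
    tied modes (e.g. a 2-2 split over four ratings) take the smaller value
    and raise the flag, marking subjects that need manual consensus.
    """
    r = np.asarray(ratings)
    if r.ndim != 2:
        raise ValueError("ratings must be (n_subjects, n_ratings)")
    modes = np.empty(r.shape[0], dtype=r.dtype)
    ties = np.zeros(r.shape[0], dtype=bool)
    for i, row in enumerate(r):
        vals, counts = np.unique(row, return_counts=True)
        top = counts.max()
        winners = vals[counts == top]
        modes[i] = winners.min()
        ties[i] = len(winners) > 1
    return modes, ties
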