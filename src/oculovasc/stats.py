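"""Clustered inference for two-eyes-per-subject designs.

Eyes from the same subject are correlated, so group contrasts and
disability associations are estimated with generalized estimating
equations (GEE): a linear mean model, an exchangeable working correlation
(equal correlation for any pair of eyes within a subject) and the robust
sandwich variance estimator, which is consistent even when the working
correlation is wrong.  Multiplicity is handled with Benjamini–Hochberg
false-discovery-rate adjustment per model family, and small-sample group
contrasts fall back on the Wilcoxon rank-sum test with exact enumeration
where feasible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "annual_progression",
    "GeeFit",
    "gee_fit",
    "bh_fdr",
    "wilcoxon_rank_sum",
    "cohort_table",
    "MODEL_PRESETS",
    "fit_models",
]


def annual_progression(edss_dx: float, edss_visit: float, years_since_dx: float) -> float:
    """Annual disability progression: (EDSS at visit − EDSS at diagnosis)
    divided by years since diagnosis.  Negative values (improvement) are
    allowed."""
    if years_since_dx <= 0:
        raise ValueError("years_since_dx must be positive")
    return (edss_visit - edss_dx) / years_since_dx


# ---------------------------------------------------------------------------
# GEE with exchangeable working correlation


@dataclass
class GeeFit:
    """Linear GEE fit with robust (sandwich) inference."""

    params: pd.Series
    robust_se: pd.Series
    ci_lo: pd.Series
    ci_hi: pd.Series
    pvalues: pd.Series
    rho_hat: float
    scale: float
    n_clusters: int
    n_obs: int
    converged: bool
    n_iter: int
    outcome: str = ""


def _design_matrix(df: pd.DataFrame, terms, reference: dict[str, str]) -> pd.DataFrame:
    """Intercept + main-effect design; categoricals are dummy-coded
    against the stated reference level."""
    cols = {"Intercept": np.ones(len(df))}
    for t in terms:
        s = df[t]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = sorted(s.astype(str).unique())
            ref = reference.get(t, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent in {t!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols[f"{t}[{lev}]"] = (s.astype(str) == lev).astype(float).to_numpy()
        else:
            cols[t] = s.astype(float).to_numpy()
    X = pd.DataFrame(cols, index=df.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the caller
        _, r = np.linalg.qr(X.to_numpy())
        dep = [X.columns[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"design matrix rank deficient; collinear columns: {dep}")
    return X


def _exchangeable_inverse(n: int, rho: float) -> np.ndarray:
    """Closed-form inverse of the n×n exchangeable correlation matrix
    R = (1-rho)I + rho*J, by Sherman–Morrison."""
    if n == 1:
        return np.ones((1, 1))
    off = -rho / ((1.0 - rho) * (1.0 + (n - 1) * rho))
    diag = 1.0 / (1.0 - rho) + off
    return off * np.ones((n, n)) + (diag - off) * np.eye(n)


def gee_fit(
    df: pd.DataFrame,
    outcome: str,
    terms,
    cluster: str = "subject_id",
    reference: dict[str, str] | None = None,
    working: str = "exchangeable",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GeeFit:
    """Linear GEE with exchangeable (or independence) working correlation.

    Iterates between (1) solving the weighted estimating equations for
    beta given the working correlation and (2) re-estimating the
    dispersion and the within-cluster correlation rho from Pearson
    residuals, until ``max |Δbeta| < tol``.  Variance is the robust
    sandwich estimator; 95% CIs use the 1.96 normal multiplier and
    p-values the normal reference.  With singleton clusters the estimate
    reduces exactly to ordinary least squares.
    """
    if working not in ("exchangeable", "independence"):
        raise ValueError("working must be 'exchangeable' or 'independence'")
    reference = reference or {}
    data = df.dropna(subset=[outcome, cluster, *terms])
    X = _design_matrix(data, terms, reference)
    y = data[outcome].astype(float).to_numpy()
    names = list(X.columns)
    Xv = X.to_numpy()
    n_obs, p = Xv.shape
    groups = data[cluster].to_numpy()
    _, idx = np.unique(groups, return_index=True)
    cluster_ids = groups[np.sort(idx)]
    members = [np.flatnonzero(groups == g) for g in cluster_ids]
    n_clusters = len(members)
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters")

    beta = np.linalg.lstsq(Xv, y, rcond=None)[0]  # OLS start
    rho = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - Xv @ beta
        scale = float(resid @ resid) / max(n_obs - p, 1)
        if working == "exchangeable":
            num, den = 0.0, 0
            for m in members:
                r = resid[m]
                k = len(r)
                if k > 1:
                    num += (r.sum() ** 2 - (r ** 2).sum()) / 2.0
                    den += k * (k - 1) // 2
            den_adj = max(den - p, 1)
            rho_new = num / (scale * den_adj) if den > 0 and scale > 0 else 0.0
            rho_new = float(np.clip(rho_new, -0.99, 0.99))
        else:
            rho_new = 0.0
        A = np.zeros((p, p))
        b = np.zeros(p)
        for m in members:
            Xi, yi = Xv[m], y[m]
            Rinv = _exchangeable_inverse(len(m), rho_new)
            XtR = Xi.T @ Rinv
            A += XtR @ Xi
            b += XtR @ yi
        beta_new = np.linalg.solve(A, b)
        delta = float(np.max(np.abs(beta_new - beta)))
        beta, rho = beta_new, rho_new
        if delta < tol:
            converged = True
            break
    resid = y - Xv @ beta
    scale = float(resid @ resid) / max(n_obs - p, 1)
    A = np.zeros((p, p))
    B = np.zeros((p, p))
    for m in members:
        Xi, ri = Xv[m], resid[m]
        Rinv = _exchangeable_inverse(len(m), rho)
        XtR = Xi.T @ Rinv
        A += XtR @ Xi
        u = XtR @ ri
        B += np.outer(u, u)
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv
    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    return GeeFit(
        params=pd.Series(beta, index=names),
        robust_se=pd.Series(se, index=names),
        ci_lo=pd.Series(beta - 1.96 * se, index=names),
        ci_hi=pd.Series(beta + 1.96 * se, index=names),
        pvalues=pd.Series(pvals, index=names),
        rho_hat=float(rho),
        scale=scale,
        n_clusters=n_clusters,
        n_obs=n_obs,
        converged=converged,
        n_iter=it,
        outcome=outcome,
    )


# ---------------------------------------------------------------------------
# multiplicity and rank tests


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p-values and rejection set.

    ``adj_i = min_{j >= i} p_(j) * m / j`` (capped at 1) on the sorted
    p-values; rejection where the adjusted value is <= alpha.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj <= alpha


def _ranksum_counts(n: int, N: int) -> np.ndarray:
    """counts[s] = number of n-subsets of {1..N} with rank sum s."""
    max_sum = n * N
    table = np.zeros((n + 1, max_sum + 1), dtype=object)
    table[0, 0] = 1
    for value in range(1, N + 1):
        for k in range(min(value, n), 0, -1):
            table[k, value:] = table[k, value:] + table[k - 1, :-value].copy()
    return table[n]


def wilcoxon_rank_sum(x, y, exact_max_n: int = 20) -> dict:
    """Two-sample Wilcoxon rank-sum test.

    Exact enumeration of the rank-sum null distribution when the combined
    sample size is at most ``exact_max_n`` and there are no ties;
    otherwise mid-ranks with a normal approximation including tie and
    continuity corrections.  The two-sided exact p is
    ``min(1, 2*min(P(W<=w), P(W>=w)))``.  Identical samples return p = 1
    flagged degenerate.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return {"statistic": float(len(x) * (len(x) + 1) / 2), "p": 1.0,
                "method": "degenerate", "degenerate": True}
    n, m = len(x), len(y)
    N = n + m
    ranks = sps.rankdata(combined)
    w = float(ranks[:n].sum())
    has_ties = len(np.unique(combined)) < N
    if N <= exact_max_n and not has_ties:
        counts = _ranksum_counts(n, N)
        total = math.comb(N, n)
        wi = int(round(w))
        p_le = sum(counts[: wi + 1]) / total
        p_ge = sum(counts[wi:]) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        mean = n * (N + 1) / 2.0
        tie_counts = np.unique(combined, return_counts=True)[1]
        tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (N * (N - 1))
        var = n * m / 12.0 * (N + 1 - tie_term)
        z = (abs(w - mean) - 0.5) / math.sqrt(var)
        p = float(2.0 * sps.norm.sf(max(z, 0.0)))
        method = "normal-approx-ties" if has_ties else "normal-approx"
    return {"statistic": w, "p": min(p, 1.0), "method": method, "degenerate": False}


# ---------------------------------------------------------------------------
# descriptive cohort summaries


def _continuous_rows(s: pd.Series) -> dict[str, str]:
    s = s.dropna().astype(float)
    q1, med, q3 = np.percentile(s, [25, 50, 75]) if len(s) else (np.nan,) * 3
    return {
        "Mean (SD)": f"{s.mean():.2f} ({s.std(ddof=1) if len(s) > 1 else 0:.2f})",
        "Median (IQR)": f"{med:.2f} ({q1:.2f}, {q3:.2f})",
        "Range": f"{s.min():.2f}, {s.max():.2f}",
    }


def cohort_table(
    records: pd.DataFrame,
    group_col: str = "group",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Descriptive cohort summary with group-comparison tests.

    Continuous variables are summarised as mean (SD), median (IQR) and
    range and compared with the Kruskal–Wallis rank-sum test; categorical
    variables as counts (%) with a Pearson chi-square test, switching to
    Fisher's exact test for 2×2 tables with any expected cell below 5.
    Empty groups are omitted with a note.
    """
    if records.empty:
        raise ValueError("no records")
    groups = [g for g, sub in records.groupby(group_col) if len(sub)]
    continuous = continuous or []
    categorical = categorical or []
    rows = []
    for var in continuous:
        samples = [records.loc[records[group_col] == g, var].dropna() for g in groups]
        usable = [s for s in samples if len(s)]
        if len(usable) >= 2:
            p = float(sps.kruskal(*usable).pvalue)
            test = "kruskal-wallis"
        else:
            p, test = np.nan, "none"
        for i, g in enumerate(groups):
            stats_rows = _continuous_rows(samples[i]) if len(samples[i]) else {}
            for stat, text in stats_rows.items():
                rows.append({"variable": var, "statistic": stat, "group": g,
                             "value": text, "p": p, "test": test})
    for var in categorical:
        ct = pd.crosstab(records[var], records[group_col])
        ct = ct[[g for g in groups if g in ct.columns]]
        expected = sps.chi2_contingency(ct.to_numpy())[3] if ct.size else np.array([[5]])
        if ct.shape == (2, 2) and (expected < 5).any():
            p = float(sps.fisher_exact(ct.to_numpy())[1])
            test = "fisher-exact"
        else:
            p = float(sps.chi2_contingency(ct.to_numpy())[1])
            test = "chi-square"
        for level in ct.index:
            for g in ct.columns:
                n = int(ct.loc[level, g])
                tot = int(ct[g].sum())
                rows.append({"variable": var, "statistic": str(level), "group": g,
                             "value": f"{n} ({100 * n / tot:.1f}%)", "p": p, "test": test})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model presets mirroring the study's analysis plan


@dataclass(frozen=True)
class ModelPreset:
    name: str
    exposure: str
    covariates: tuple[str, ...] = ()
    subset_groups: tuple[str, ...] = ()
    reference: tuple[tuple[str, str], ...] = (("group", "Ctrl"),)


MODEL_PRESETS: dict[str, ModelPreset] = {
    # group contrasts vs control eyes, unadjusted and adjusted for the
    # covariates associated with exposure (IOP and hypertension)
    "group_unadjusted": ModelPreset("group_unadjusted", "group"),
    "group_adjusted": ModelPreset("group_adjusted", "group", ("iop", "hypertension")),
    # disability models in MSnON eyes, adjusted for age, sex, refractive
    # error and hypertension
    "edss": ModelPreset(
        "edss", "edss_visit", ("age", "sex", "spherical_error", "hypertension"),
        subset_groups=("MSnON",), reference=()),
    "edss_progression": ModelPreset(
        "edss_progression", "edss_progression",
        ("age", "sex", "spherical_error", "hypertension"),
        subset_groups=("MSnON",), reference=()),
}


def fit_models(
    df: pd.DataFrame,
    outcomes: list[str],
    preset: ModelPreset | str = "group_adjusted",
    cluster: str = "subject_id",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit one GEE per outcome under a named model preset.

    Returns a tidy frame (outcome, term, beta, se, ci_lo, ci_hi, p) with
    BH-FDR-adjusted p-values computed over the exposure terms of the whole
    family (one family per results table).
    """
    if isinstance(preset, str):
        preset = MODEL_PRESETS[preset]
    data = df
    if preset.subset_groups:
        data = df[df["group"].isin(preset.subset_groups)]
    terms = [preset.exposure, *preset.covariates]
    rows = []
    for outcome in outcomes:
        try:
            fit = gee_fit(data, outcome, terms, cluster=cluster,
                          reference=dict(preset.reference))
        except (ValueError, np.linalg.LinAlgError):
            continue
        for term in fit.params.index:
            rows.append({
                "model": preset.name, "outcome": outcome, "term": term,
                "beta": fit.params[term], "se": fit.robust_se[term],
                "ci_lo": fit.ci_lo[term], "ci_hi": fit.ci_hi[term],
                "p": fit.pvalues[term], "rho_hat": fit.rho_hat,
                "n_eyes": fit.n_obs, "n_subjects": fit.n_clusters,
                "converged": fit.converged,
            })
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    is_exposure = res["term"].str.startswith(preset.exposure)
    res["p_fdr"] = np.nan
    if is_exposure.any():
        adj, _ = bh_fdr(res.loc[is_exposure, "p"].to_numpy(), alpha=alpha)
        res.loc[is_exposure, "p_fdr"] = adj
    return res
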