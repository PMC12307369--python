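"""Group statistics: normality-gated comparisons, post hoc corrections,
partial and rank correlations, chi-square for categorical tables.

Routing follows the usual clinical-neuroimaging convention: Shapiro-Wilk
per group at alpha = 0.05; if every group passes, ANCOVA with Bonferroni
post hoc, otherwise Kruskal-Wallis with Dunn's z-tests (Bonferroni over
the pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.formula.api import ols


class StatsError(ValueError):
    """Raised for degenerate or invalid statistical inputs."""


@dataclass
class GroupTestResult:
    method: str  # "ANCOVA" | "Kruskal-Wallis"
    statistic: float  # F or H
    p_overall: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    adjustment: str = ""


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    p: float
    n_effective: int
    covariates: tuple[str, ...] = ()


def _group_arrays(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    return {g: values[groups == g] for g in pd.unique(groups)}


def normality_gate(values, groups, alpha: float = 0.05) -> str:
    """Shapiro-Wilk per group; "parametric" iff every group passes.

    Constant-valued groups are clearly non-normal in the relevant sense
    and route to "nonparametric" rather than raising.
    """
    by_group = _group_arrays(values, groups)
    for g, x in by_group.items():
        if len(x) < 3:
            raise StatsError(f"group '{g}' has fewer than 3 values")
        if np.ptp(x) == 0:
            return "nonparametric"
        if sps.shapiro(x).pvalue < alpha:
            return "nonparametric"
    return "parametric"


# largest total sample for which the Kruskal-Wallis p is computed by
# exhaustive permutation instead of the chi-square approximation (which
# is inaccurate for very small samples)
KRUSKAL_EXACT_MAX_N = 10


def _kruskal_exact_p(rank_groups: list[np.ndarray], h_obs: float) -> float:
    """Exact permutation p: enumerate every distinct assignment of the
    pooled ranks to the group sizes and count H >= observed."""
    ranks = np.concatenate(rank_groups)
    sizes = [len(g) for g in rank_groups]
    n = len(ranks)
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_corr = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)

    def h_stat(assign: list[np.ndarray]) -> float:
        h = 12.0 / (n * (n + 1)) * sum(
            a.sum() ** 2 / len(a) for a in assign
        ) - 3 * (n + 1)
        return h / tie_corr if tie_corr > 0 else 0.0

    count = total = 0
    idx = np.arange(n)

    def rec(remaining: np.ndarray, gi: int, acc: list[np.ndarray]) -> None:
        nonlocal count, total
        if gi == len(sizes) - 1:
            total += 1
            if h_stat(acc + [ranks[remaining]]) >= h_obs - 1e-12:
                count += 1
            return
        from itertools import combinations as comb

        for pick in comb(range(len(remaining)), sizes[gi]):
            sel = remaining[list(pick)]
            rest = np.delete(remaining, list(pick))
            rec(rest, gi + 1, acc + [ranks[sel]])

    rec(idx, 0, [])
    return count / total


def kruskal_dunn(values, groups) -> GroupTestResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's post hoc z-tests,
    Bonferroni-adjusted over all group pairs.

    The overall p uses the chi-square approximation with k-1 df, except
    for very small samples (total n <= 10) where it is computed exactly
    by enumerating all permutations of the group assignment.  Dunn's z
    for groups i, j compares mean ranks with the tie-corrected pooled
    variance (N(N+1)/12 - T)(1/n_i + 1/n_j), where
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
    """
    by_group = _group_arrays(values, groups)
    names = list(by_group)
    if len(names) < 2:
        raise StatsError("need at least two groups")
    pooled = np.concatenate([by_group[g] for g in names])
    n_total = len(pooled)
    if n_total < 5:
        raise StatsError("need total n >= 5")
    if np.ptp(pooled) == 0:
        raise StatsError("all values identical; H is undefined")

    h, p = sps.kruskal(*[by_group[g] for g in names])

    ranks = sps.rankdata(pooled)
    if n_total <= KRUSKAL_EXACT_MAX_N:
        offs = np.cumsum([0] + [len(by_group[g]) for g in names])
        rank_groups = [ranks[offs[i]: offs[i + 1]] for i in range(len(names))]
        p = _kruskal_exact_p(rank_groups, float(h))
    offsets = np.cumsum([0] + [len(by_group[g]) for g in names])
    mean_ranks = {
        g: ranks[offsets[i]: offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(names, 2))
    pairwise = {}
    for a, b in pairs:
        se = np.sqrt(base_var * (1 / len(by_group[a]) + 1 / len(by_group[b])))
        if se == 0:
            raise StatsError("zero rank variance (all values tied)")
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = 2 * sps.norm.sf(abs(z))
        pairwise[(a, b)] = min(1.0, len(pairs) * p_raw)
    return GroupTestResult(
        method="Kruskal-Wallis",
        statistic=float(h),
        p_overall=float(p),
        pairwise=pairwise,
        adjustment="Dunn+Bonferroni",
    )


def ancova_bonferroni(values, groups, covariates: pd.DataFrame | None = None) -> GroupTestResult:
    """Linear model value ~ group + covariates; overall group F-test;
    pairwise contrasts on the adjusted means, Bonferroni-corrected.

    With common slopes the adjusted-mean difference between two groups
    equals the difference of their group coefficients, so the pairwise
    tests are t-tests on coefficient contrasts.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    df = pd.DataFrame({"y": values, "grp": groups})
    cov_names: list[str] = []
    if covariates is not None and len(covariates.columns) > 0:
        for c in covariates.columns:
            df[c] = np.asarray(covariates[c], dtype=float)
        cov_names = list(covariates.columns)
    formula = "y ~ C(grp)" + "".join(f" + {c}" for c in cov_names)
    n_params = len(pd.unique(groups)) + len(cov_names)
    if len(df) <= n_params + 1:
        raise StatsError("not enough observations for the model")
    model = ols(formula, data=df)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        bad = _collinear_columns(model.exog, model.exog_names)
        raise StatsError(f"design matrix is rank deficient (columns: {bad})")
    res = model.fit()
    anova = sm.stats.anova_lm(res, typ=2)
    f_stat = float(anova.loc["C(grp)", "F"])
    p_overall = float(anova.loc["C(grp)", "PR(>F)"])

    names = list(pd.unique(groups))
    pairs = list(combinations(names, 2))
    pairwise = {}
    for a, b in pairs:
        contrast = np.zeros(len(res.params))
        for g, sign in ((a, 1.0), (b, -1.0)):
            term = f"C(grp)[T.{g}]"
            if term in res.model.exog_names:
                contrast[res.model.exog_names.index(term)] = sign
        tt = res.t_test(contrast)
        pairwise[(a, b)] = min(1.0, len(pairs) * float(tt.pvalue))
    return GroupTestResult(
        method="ANCOVA",
        statistic=f_stat,
        p_overall=p_overall,
        pairwise=pairwise,
        adjustment="Bonferroni",
    )


def _collinear_columns(exog: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    base_rank = np.linalg.matrix_rank(exog)
    for j, name in enumerate(names):
        reduced = np.delete(exog, j, axis=1)
        if np.linalg.matrix_rank(reduced) == base_rank:
            bad.append(name)
    return bad


def group_compare(values, groups, covariates: pd.DataFrame | None = None) -> GroupTestResult:
    """Normality-gated comparison: ANCOVA if every group passes
    Shapiro-Wilk, otherwise Kruskal-Wallis with Dunn's post hoc."""
    if normality_gate(values, groups) == "parametric":
        return ancova_bonferroni(values, groups, covariates)
    return kruskal_dunn(values, groups)


def partial_corr(x, y, covariates: pd.DataFrame | np.ndarray | None = None) -> CorrelationResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualised on [1, covariates] by least squares;
    r is the Pearson correlation of the residuals and p comes from the t
    distribution with n - 2 - k degrees of freedom.  With no covariates
    this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        cov = np.empty((n, 0))
        cov_names: tuple[str, ...] = ()
    elif isinstance(covariates, pd.DataFrame):
        cov = covariates.to_numpy(dtype=float)
        cov_names = tuple(covariates.columns)
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cov_names = tuple(f"c{i}" for i in range(cov.shape[1]))
    k = cov.shape[1]
    if n <= k + 2:
        raise StatsError("need n > number of covariates + 2")
    design = np.column_stack([np.ones(n), cov])
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    sx, sy = np.sqrt(np.sum(rx**2)), np.sqrt(np.sum(ry**2))
    # relative tolerance: a variable numerically collinear with the
    # covariates leaves only floating-point noise as residual
    tol_x = 1e-8 * max(np.sqrt(np.sum((x - x.mean()) ** 2)), 1e-30)
    tol_y = 1e-8 * max(np.sqrt(np.sum((y - y.mean()) ** 2)), 1e-30)
    if sx <= tol_x or sy <= tol_y:
        raise StatsError("zero residual variance after removing covariates")
    r = float(np.sum(rx * ry) / (sx * sy))
    df_t = n - 2 - k
    r_clip = min(max(r, -1.0), 1.0)
    if abs(r_clip) >= 1.0:
        p = 0.0
    else:
        t = r_clip * np.sqrt(df_t / (1 - r_clip**2))
        p = float(2 * sps.t.sf(abs(t), df_t))
    return CorrelationResult(r=r, r_squared=r * r, p=p, n_effective=n, covariates=cov_names)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation (tie-averaged ranks, t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise StatsError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("constant input; rank correlation undefined")
    res = sps.spearmanr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, p=float(res.pvalue), n_effective=len(x))


def chi_square_counts(table) -> tuple[float, float]:
    """Pearson chi-square on a contingency table of counts, no continuity
    correction; df = (rows - 1)(cols - 1)."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.rint(table)):
        raise StatsError("table must hold non-negative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise StatsError("table has a zero margin")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


DEFAULT_ANCOVA_COVARIATES = ("age", "sex", "education")
DEFAULT_PARTIAL_COVARIATES = ("age", "sex", "education", "total_brain_volume_mm3")

IMAGING_METRICS = (
    "epvs_total_volume", "epvs_total_number", "bg_fraction", "cso_fraction",
    "alps_left", "alps_right", "alps_mean",
)


def cohort_analysis(table: pd.DataFrame) -> dict:
    """Run the full statistical battery on a per-subject cohort table.

    Expects columns: group, age, sex, education, total_brain_volume_mm3,
    mmse, moca, and whichever of the imaging metrics are present.
    Returns group comparisons per metric, partial correlations of each
    metric with MMSE/MoCA, Spearman correlations of ALPS with EPVS
    metrics, and the sex-by-group chi-square.
    """
    out: dict = {"group_tests": {}, "partial_correlations": {},
                 "spearman_alps_epvs": {}, "sex_chi_square": None}
    groups = table["group"].to_numpy()
    cov_cols = [c for c in DEFAULT_ANCOVA_COVARIATES if c in table.columns]
    ancova_covs = table[cov_cols] if cov_cols else None
    metrics = [m for m in IMAGING_METRICS if m in table.columns]
    for m in metrics:
        res = group_compare(table[m].to_numpy(), groups, ancova_covs)
        out["group_tests"][m] = res
    pc_cols = [c for c in DEFAULT_PARTIAL_COVARIATES if c in table.columns]
    for m in metrics:
        for score in ("mmse", "moca"):
            if score in table.columns:
                out["partial_correlations"][(m, score)] = partial_corr(
                    table[m], table[score],
                    table[pc_cols] if pc_cols else None,
                )
    if "alps_mean" in table.columns:
        for m in ("epvs_total_volume", "epvs_total_number", "bg_fraction", "cso_fraction"):
            if m in table.columns:
                out["spearman_alps_epvs"][m] = spearman(table["alps_mean"], table[m])
    if "sex" in table.columns:
        counts = pd.crosstab(table["sex"], table["group"]).to_numpy()
        out["sex_chi_square"] = chi_square_counts(counts)
    return out
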