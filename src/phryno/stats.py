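"""Phylogenetic regression and hypothesis tests.

PGLS fits a linear model by generalized least squares with a Brownian-motion
residual covariance built from the tree (optionally Pagel's lambda-scaled);
on a star tree it reduces exactly to OLS. The phylogenetic ANOVA compares an
observed one-way F statistic against F statistics from Brownian simulations
on the same tree. The stochastic-linear-OU ("evolutionary vs optimal
regression") model profiles a grid over the phylogenetic half-life t1/2 and
the stationary residual variance vy: at each grid point the observed
("evolutionary") slope is estimated by GLS under the OU residual covariance,
and the underlying ("optimal") slope is recovered by dividing out the
phylogenetic attenuation factor

    rho(alpha) = 1 - (1 - e^{-alpha T}) / (alpha T),

which tends to 1 as t1/2 -> 0 (instantaneous adaptation) and to 0 as
t1/2 -> inf, so |evolutionary slope| <= |optimal slope| always.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .tree import PhyloTree, mrca_depth_matrix

__all__ = [
    "PGLSResult", "PhylAnovaResult", "SlouchFit",
    "pgls", "phyl_anova", "slouch_fit", "mann_whitney", "two_sample_t",
]

BONFERRONI_TWO_GROUP = 0.025     # level applied when parity modes are fitted separately


# ----------------------------------------------------------------- PGLS
@dataclass
class PGLSResult:
    params: pd.Series
    pvalues: pd.Series
    bse: pd.Series
    n: int
    correlation: str                  # "BM" or "lambda"
    lambda_: float | None = None
    alpha_level: float = 0.05
    group: str | None = None
    interaction_pvalue: float | None = None
    species: list = field(default_factory=list)

    @property
    def slope(self) -> float:
        non_const = [k for k in self.params.index if k != "const"]
        return float(self.params[non_const[0]])

    @property
    def intercept(self) -> float:
        return float(self.params["const"])


def _bm_corr(tree: PhyloTree, labels, lam: float | None):
    sub = tree.prune_to(labels) if set(labels) != set(tree.tip_labels) else tree
    C = mrca_depth_matrix(sub)
    if lam is not None:
        D = np.diag(np.diag(C))
        C = lam * (C - D) + D
    order = [sub.tip_labels.index(l) for l in labels]
    return C[np.ix_(order, order)]


def _gls_fit(y, X, C):
    model = sm.GLS(y, X, sigma=C)
    return model.fit()


def pgls(tree: PhyloTree, data: pd.DataFrame, y: str, x, by: str | None = None,
         lambda_: float | None = None, interaction: bool = False):
    """Phylogenetic GLS regression of column `y` on column(s) `x`.

    Proceeds on the tip-intersection of tree and complete cases of `data`
    (indexed by species). With ``by`` set to a binary grouping column (parity
    mode), one regression is fitted per group and the Bonferroni-corrected
    level 0.025 is recorded on each result; with ``interaction=True`` a
    pooled model with a group x predictor interaction is fitted instead and
    the interaction p-value reported.
    """
    xcols = [x] if isinstance(x, str) else list(x)
    cols = [y] + xcols + ([by] if by else [])
    df = data[cols].dropna()
    df.index = [str(s).strip() for s in df.index]
    keep = [l for l in tree.tip_labels if l in set(df.index)]
    if len(keep) < len(xcols) + 2:
        raise ValueError("too few complete cases on the tree")
    df = df.loc[keep]
    C = _bm_corr(tree, keep, lambda_)
    corr = "BM" if lambda_ is None else "lambda"

    def fit_one(sub_df, sub_labels, group=None, alpha_level=0.05):
        X = sm.add_constant(sub_df[xcols])
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(f"design matrix is rank deficient (columns {xcols})")
        idx = [keep.index(l) for l in sub_labels]
        res = _gls_fit(sub_df[y], X, C[np.ix_(idx, idx)])
        return PGLSResult(res.params, res.pvalues, res.bse, len(sub_df), corr,
                          lambda_, alpha_level, group, species=list(sub_labels))

    if by is None:
        return fit_one(df, keep)

    groups = sorted(df[by].unique())
    if interaction:
        X = sm.add_constant(pd.DataFrame({
            c: df[c] for c in xcols
        }))
        g = (df[by] == groups[-1]).astype(float)
        X[by] = g
        for c in xcols:
            X[f"{c}:{by}"] = df[c] * g
        res = _gls_fit(df[y], X, C)
        out = PGLSResult(res.params, res.pvalues, res.bse, len(df), corr, lambda_,
                         species=keep)
        out.interaction_pvalue = float(res.pvalues[f"{xcols[0]}:{by}"])
        return out
    results = {}
    for gval in groups:
        sub = df[df[by] == gval]
        labels = [l for l in keep if l in set(sub.index)]
        results[gval] = fit_one(sub.loc[labels], labels, group=str(gval),
                                alpha_level=BONFERRONI_TWO_GROUP)
    return results


# --------------------------------------------------------------- phylANOVA
@dataclass
class PhylAnovaResult:
    F: float
    pvalue: float
    n_sim: int
    seed: int
    n_per_group: dict = field(default_factory=dict)


def _anova_F(y: np.ndarray, g: np.ndarray) -> float:
    grand = y.mean()
    ssb = ssw = 0.0
    k = 0
    for lvl in np.unique(g):
        yi = y[g == lvl]
        ssb += yi.size * (yi.mean() - grand) ** 2
        ssw += ((yi - yi.mean()) ** 2).sum()
        k += 1
    dfb, dfw = k - 1, y.size - k
    if ssw == 0:
        return 0.0 if ssb == 0 else np.inf
    return (ssb / dfb) / (ssw / dfw)


def phyl_anova(tree: PhyloTree, group: pd.Series, y: pd.Series, n_sim: int = 500,
               seed: int = 0) -> PhylAnovaResult:
    """Simulation-based phylogenetic ANOVA.

    The null distribution of the one-way F statistic is generated by
    simulating Brownian motion on the tree (sigma2 estimated from the data by
    ML) and the p-value is (r + 1)/(n_sim + 1) where r counts simulated
    F >= observed, so p is never exactly zero.
    """
    y = pd.Series(y).dropna()
    group = pd.Series(group)
    labels = [l for l in tree.tip_labels if l in set(y.index) and l in set(group.index)]
    sub = tree.prune_to(labels) if set(labels) != set(tree.tip_labels) else tree
    yv = y.loc[sub.tip_labels].to_numpy(dtype=float)
    gv = group.loc[sub.tip_labels].to_numpy()
    if len(np.unique(gv)) < 2:
        raise ValueError("both groups must be non-empty")
    C = mrca_depth_matrix(sub)
    Ci = np.linalg.inv(C)
    one = np.ones(len(yv))
    mu = float(one @ Ci @ yv / (one @ Ci @ one))
    sig2 = float((yv - mu) @ Ci @ (yv - mu) / len(yv))
    L = np.linalg.cholesky(sig2 * C + 1e-12 * np.eye(len(yv)))
    F_obs = _anova_F(yv, gv)
    rng = np.random.default_rng(seed)
    r = 0
    for _ in range(n_sim):
        ysim = mu + L @ rng.standard_normal(len(yv))
        if _anova_F(ysim, gv) >= F_obs:
            r += 1
    p = (r + 1) / (n_sim + 1)
    counts = {str(k): int(v) for k, v in zip(*np.unique(gv, return_counts=True))}
    return PhylAnovaResult(float(F_obs), float(p), n_sim, seed, counts)


# ------------------------------------------------------------------ SLOUCH
@dataclass
class SlouchFit:
    grid: pd.DataFrame              # t_half, vy, logL, slopes per grid point
    best_t_half: float
    best_alpha: float
    best_vy: float
    evolutionary_slope: float
    optimal_slope: float
    evolutionary_intercept: float
    loglik: float
    support_set: pd.DataFrame       # grid points within 2 logL units of the max
    n: int


def attenuation(alpha: float, T: float) -> float:
    """Phylogenetic attenuation of the evolutionary vs optimal slope."""
    x = alpha * T
    if x <= 0:
        return 0.0
    if x > 700:
        return 1.0 - 1.0 / x
    return 1.0 - (1.0 - math.exp(-x)) / x


def slouch_fit(tree: PhyloTree, y: pd.Series, predictor: pd.Series,
               t_half_grid=None, vy_grid=None, n_grid: int = 50) -> SlouchFit:
    """Grid-search fit of the evolutionary/optimal regression OU model.

    At each (t1/2, vy) grid point, y is regressed on the predictor by GLS
    under the stationary OU residual covariance vy * exp(-alpha * d_ij)
    (d_ij = phylogenetic distance); the optimal slope is the evolutionary
    slope divided by the attenuation factor. The predictor is treated as a
    fixed, error-free covariate. The support set collects grid points within
    2 log-likelihood units of the maximum.
    """
    rep_labels = [l for l in tree.tip_labels
                  if l in set(pd.Series(y).dropna().index)
                  and l in set(pd.Series(predictor).dropna().index)]
    sub = tree.prune_to(rep_labels) if set(rep_labels) != set(tree.tip_labels) else tree
    yv = pd.Series(y).loc[sub.tip_labels].to_numpy(dtype=float)
    xv = pd.Series(predictor).loc[sub.tip_labels].to_numpy(dtype=float)
    n = len(yv)
    T = sub.height
    C = mrca_depth_matrix(sub)
    D = 2.0 * (T - C)                       # phylogenetic distances (ultrametric)
    np.fill_diagonal(D, 0.0)
    X = np.column_stack([np.ones(n), xv])
    if t_half_grid is None:
        t_half_grid = np.geomspace(0.01, 5.0 * T, n_grid)
    if vy_grid is None:
        v0 = np.var(yv)
        vy_grid = v0 * np.geomspace(0.05, 10.0, n_grid)
    if len(t_half_grid) < 2 or len(vy_grid) < 1:
        raise ValueError("degenerate grid")
    rows = []
    for th in t_half_grid:
        alpha = math.log(2.0) / th
        A = np.exp(-alpha * D)
        sign, logdetA = np.linalg.slogdet(A)
        Ai = np.linalg.inv(A)
        XtAi = X.T @ Ai
        beta = np.linalg.solve(XtAi @ X, XtAi @ yv)
        r = yv - X @ beta
        q = float(r @ Ai @ r)
        rho = attenuation(alpha, T)
        for vy in vy_grid:
            ll = -0.5 * (n * math.log(2 * math.pi * vy) + logdetA + q / vy)
            rows.append({"t_half": float(th), "vy": float(vy), "alpha": alpha,
                         "logL": ll, "evolutionary_slope": float(beta[1]),
                         "optimal_slope": float(beta[1]) / rho if rho > 0 else np.inf,
                         "intercept": float(beta[0])})
    grid = pd.DataFrame(rows)
    best = grid.loc[grid["logL"].idxmax()]
    support = grid[grid["logL"] >= best["logL"] - 2.0].copy()
    return SlouchFit(grid, float(best["t_half"]), float(best["alpha"]),
                     float(best["vy"]), float(best["evolutionary_slope"]),
                     float(best["optimal_slope"]), float(best["intercept"]),
                     float(best["logL"]), support, n)


# ----------------------------------------------------------- plain tests
@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    U_complement: float
    pvalue: float
    method: str


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with midrank tie handling.

    The statistic reported is the number of (x, y) pairs with x > y plus half
    the ties; its complement n1*n2 - U is also returned. The p-value is exact
    for min(n) <= 8 without ties, otherwise the tie-corrected normal
    approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(float(res.statistic),
                             float(x.size * y.size - res.statistic),
                             float(res.pvalue), method)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    pvalue: float
    pooled: bool


def two_sample_t(x, y, pooled: bool = True) -> TTestResult:
    """Two-sample t test; pooled-variance by default (df = n1 + n2 - 2),
    Welch with ``pooled=False``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if pooled and np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=pooled)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue), pooled)
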