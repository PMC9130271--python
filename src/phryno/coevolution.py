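"""Evolutionary covariation of a binary regime with continuous traits.

Two tools: a Bayesian threshold model measuring the evolutionary correlation
r between a binary character (parity mode) and a continuous trait (a climate
variable), and the Wheatsheaf index w measuring the strength of phenotypic
convergence in a focal species set (the viviparous species).

Threshold model. The binary state of tip i is the sign of an unobserved
Brownian "liability" l_i; (l, x) evolve as a correlated bivariate Brownian
motion, so jointly [l; x] ~ N([mu_l 1; mu_x 1], R (x) C) with C the BM tree
covariance and R = [[1, r*s], [r*s, s^2]] (the liability rate is fixed to 1
for identifiability; s^2 is the BM rate of the continuous trait). The MCMC
Gibbs-samples tip liabilities from their sign-truncated univariate
conditionals and updates (mu_l, mu_x, s^2, r) by random-walk
Metropolis-Hastings, with a uniform prior on r and log-uniform prior on s^2.
The chain is written as a single compiled kernel so the canonical run length
(10^6 generations, thinning 100, burn-in 2x10^5) is practical.

Wheatsheaf index. Traits are standardized per column; w is the ratio of the
mean phylogenetically penalized pairwise Euclidean distance among all
species to that among focal species, where each pairwise distance is
penalized by (1 + shared-history fraction) so that similarity between close
relatives is discounted as ancestry rather than convergence. Significance
comes from re-drawing random focal sets of the same size (bootstrap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .tree import PhyloTree, mrca_depth_matrix

__all__ = ["ThresholdChain", "WheatsheafResult", "threshold_mcmc", "wheatsheaf"]

ESS_WARNING = 100


# ----------------------------------------------------------- numba kernel
@njit(cache=True)
def _rtruncnorm(mean, sd, positive):
    """One-sided truncated normal draw (Robert's method in the far tail)."""
    a = -mean / sd if positive else mean / sd   # standardized lower bound
    if a < 2.0:
        for _ in range(200):
            z = np.random.normal()
            if z > a:
                return mean + sd * z if positive else mean - sd * z
    lam = 0.5 * (a + np.sqrt(a * a + 4.0))
    while True:
        z = a + np.random.exponential() / lam
        if np.random.random() <= np.exp(-0.5 * (z - lam) ** 2):
            return mean + sd * z if positive else mean - sd * z


@njit(cache=True)
def _joint_loglik(mu_l, mu_x, s2, z, lCl, oCl, xCl, xCx, oCx, oCo,
                  logdetC, n):
    """Joint Gaussian log-density of (l, x) given the parameters, up to a
    constant, evaluated from precomputed quadratic forms (O(1) per call).

    Includes the uniform-on-r prior (a Jacobian term in z = atanh r) and a
    flat prior on log s2 (no term: updates propose in log space).
    """
    r = np.tanh(z)
    s = np.sqrt(s2)
    det_R = s2 * (1.0 - r * r)
    if det_R <= 0 or s2 <= 0:
        return -1e300
    S11 = lCl - 2.0 * mu_l * oCl + mu_l * mu_l * oCo
    S22 = xCx - 2.0 * mu_x * oCx + mu_x * mu_x * oCo
    S12 = xCl - mu_l * oCx - mu_x * oCl + mu_l * mu_x * oCo
    # tr(R^-1 S) with R = [[1, r s], [r s, s2]]
    tr = (s2 * S11 - 2.0 * r * s * S12 + S22) / det_R
    logprior = np.log(1.0 - r * r)
    return -0.5 * (2.0 * logdetC + n * np.log(det_R) + tr) + logprior


@njit(cache=True)
def _threshold_kernel(Ci, x, pos, generations, thin, burnin, seed,
                      steps, out_params, out_liab_mean):
    """Gibbs-within-MH sampler for the bivariate threshold model.

    Ci is the inverse BM tree covariance; pos[i] is True where the observed
    state forces l_i > 0. out_params rows are (r, s2, mu_l, mu_x, loglik).
    The liability sweep maintains w = Ci l incrementally so one generation
    (a full sweep plus four MH updates) costs O(n^2).
    """
    np.random.seed(seed)
    n = x.shape[0]
    Ci1 = Ci @ np.ones(n)
    Cix = Ci @ x
    oCo = np.sum(Ci1)
    xCx = x @ Cix
    oCx = np.sum(Cix)
    _, logdetCi = np.linalg.slogdet(Ci)
    logdetC = -logdetCi

    l = np.where(pos, 1.0, -1.0)
    mu_l, mu_x = 0.0, np.mean(x)
    s2 = np.var(x) + 1e-12
    z = 0.0                                   # atanh(r)
    w = Ci @ l                                # maintained incrementally
    oCl = Ci1 @ l
    xCl = x @ w

    n_keep = (generations - burnin) // thin
    kept = 0
    liab_acc = np.zeros(n)

    for g in range(generations):
        r = np.tanh(z)
        s = np.sqrt(s2)
        # Gibbs sweep: l | x ~ N(mu_l + (r/s)(x - mu_x), (1 - r^2) C),
        # per-tip univariate conditionals truncated by the observed sign
        for i in range(n):
            m_i = mu_l + (r / s) * (x[i] - mu_x)
            t_i = w[i] - mu_l * Ci1[i] - (r / s) * (Cix[i] - mu_x * Ci1[i])
            cond_mean = m_i - (t_i - Ci[i, i] * (l[i] - m_i)) / Ci[i, i]
            cond_sd = np.sqrt((1.0 - r * r) / Ci[i, i])
            new = _rtruncnorm(cond_mean, cond_sd, pos[i])
            d = new - l[i]
            if d != 0.0:
                l[i] = new
                for j in range(n):
                    w[j] += Ci[j, i] * d
                oCl += Ci1[i] * d
                xCl += Cix[i] * d
        lCl = l @ w

        cur = _joint_loglik(mu_l, mu_x, s2, z, lCl, oCl, xCl, xCx, oCx, oCo,
                            logdetC, n)
        prop = mu_l + steps[0] * np.random.normal()
        new = _joint_loglik(prop, mu_x, s2, z, lCl, oCl, xCl, xCx, oCx, oCo,
                            logdetC, n)
        if np.log(np.random.random()) < new - cur:
            mu_l, cur = prop, new
        prop = mu_x + steps[1] * np.random.normal()
        new = _joint_loglik(mu_l, prop, s2, z, lCl, oCl, xCl, xCx, oCx, oCo,
                            logdetC, n)
        if np.log(np.random.random()) < new - cur:
            mu_x, cur = prop, new
        prop = s2 * np.exp(steps[2] * np.random.normal())   # symmetric in log s2
        new = _joint_loglik(mu_l, mu_x, prop, z, lCl, oCl, xCl, xCx, oCx, oCo,
                            logdetC, n)
        if np.log(np.random.random()) < new - cur:
            s2, cur = prop, new
        prop = z + steps[3] * np.random.normal()
        new = _joint_loglik(mu_l, mu_x, s2, prop, lCl, oCl, xCl, xCx, oCx, oCo,
                            logdetC, n)
        if np.log(np.random.random()) < new - cur:
            z, cur = prop, new

        # joint (r, l) "transport" move: rescale liability deviations from the
        # conditional mean so they stay fixed in standardized units. Without
        # it the correlation freezes: liabilities sampled at the current r
        # make any solo change of r nearly impossible to accept near |r| = 1.
        prop = z + steps[3] * np.random.normal()
        r_old, r_new = np.tanh(z), np.tanh(prop)
        kappa = np.sqrt((1.0 - r_new * r_new) / (1.0 - r_old * r_old))
        s = np.sqrt(s2)
        ok = True
        l_new = np.empty(n)
        for i in range(n):
            m_old = mu_l + (r_old / s) * (x[i] - mu_x)
            m_new = mu_l + (r_new / s) * (x[i] - mu_x)
            l_new[i] = m_new + kappa * (l[i] - m_old)
            if (l_new[i] > 0.0) != pos[i]:
                ok = False
                break
        if ok:
            w_new = Ci @ l_new
            lCl_new = l_new @ w_new
            oCl_new = Ci1 @ l_new
            xCl_new = x @ w_new
            new = _joint_loglik(mu_l, mu_x, s2, prop, lCl_new, oCl_new, xCl_new,
                                xCx, oCx, oCo, logdetC, n) + n * np.log(kappa)
            if np.log(np.random.random()) < new - cur:
                z = prop
                l = l_new
                w = w_new
                lCl, oCl, xCl = lCl_new, oCl_new, xCl_new
                cur = new - n * np.log(kappa)

        if g >= burnin and (g - burnin) % thin == 0 and kept < n_keep:
            out_params[kept, 0] = np.tanh(z)
            out_params[kept, 1] = s2
            out_params[kept, 2] = mu_l
            out_params[kept, 3] = mu_x
            out_params[kept, 4] = cur
            liab_acc += l
            kept += 1
    if kept > 0:
        out_liab_mean[:] = liab_acc / kept
    return kept


# ------------------------------------------------------------- public API
@dataclass
class ThresholdChain:
    samples: pd.DataFrame            # columns r, sigma2_x, mu_liab, mu_x, loglik
    liability_mean: pd.Series
    generations: int
    thin: int
    burnin: int
    seed: int
    ess_r: float = np.nan
    low_ess: bool = False

    @property
    def r_mean(self) -> float:
        return float(self.samples["r"].mean())

    def r_interval(self, prob: float = 0.95) -> tuple[float, float]:
        q = (1 - prob) / 2
        return (float(self.samples["r"].quantile(q)),
                float(self.samples["r"].quantile(1 - q)))


def threshold_mcmc(tree: PhyloTree, binary_trait: pd.Series, continuous_trait: pd.Series,
                   generations: int = 1_000_000, thin: int = 100,
                   burnin: int = 200_000, seed: int = 0) -> ThresholdChain:
    """Sample the posterior of the liability-trait correlation r.

    Both traits are restricted to their shared tip set; the binary trait may
    be 0/1 or two string labels (sorted order maps to negative/positive
    liability). Retained draws number (generations - burnin) / thin.
    """
    b = pd.Series(binary_trait).dropna()
    xs = pd.Series(continuous_trait).dropna()
    labels = [l for l in tree.tip_labels if l in set(b.index) and l in set(xs.index)]
    if len(labels) < 5:
        raise ValueError("too few species shared by tree and both traits")
    sub = tree.prune_to(labels) if set(labels) != set(tree.tip_labels) else tree
    bv = b.loc[sub.tip_labels]
    uniq = sorted(pd.unique(bv))
    if len(uniq) != 2:
        raise ValueError(f"binary trait must have two states, got {uniq}")
    pos = (bv == uniq[1]).to_numpy()
    x = xs.loc[sub.tip_labels].to_numpy(dtype=float)
    C = mrca_depth_matrix(sub)
    # scale the tree to unit height: the liability BM rate is fixed at 1,
    # so the time unit is absorbed into the (unidentifiable) rate anyway
    C = C / sub.height
    Ci = np.linalg.inv(C + 1e-10 * np.eye(len(x)))
    n_keep = (generations - burnin) // thin
    out = np.empty((n_keep, 5))
    liab = np.empty(len(x))
    steps = np.array([0.4, 0.4 * max(np.std(x), 1e-6), 0.3, 0.15])
    kept = _threshold_kernel(Ci, x, pos, generations, thin, burnin,
                             int(seed) % (2 ** 31), steps, out, liab)
    samples = pd.DataFrame(out[:kept],
                           columns=["r", "sigma2_x", "mu_liab", "mu_x", "loglik"])
    chain = ThresholdChain(samples, pd.Series(liab, index=sub.tip_labels),
                           generations, thin, burnin, seed)
    try:
        import arviz as az
        chain.ess_r = float(az.ess(samples["r"].to_numpy()))
    except Exception:
        chain.ess_r = np.nan
    chain.low_ess = bool(np.isfinite(chain.ess_r) and chain.ess_r < ESS_WARNING)
    return chain


# -------------------------------------------------------------- Wheatsheaf
@dataclass
class WheatsheafResult:
    w: float
    pvalue: float
    n_boot: int
    focal: list = field(default_factory=list)
    traits: list = field(default_factory=list)
    seed: int = 0


def _penalized_distances(Z: np.ndarray, shared_frac: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances inflated by (1 + shared-history
    fraction): the relatedness penalty that discounts similarity inherited
    from a recent common ancestor."""
    diff = Z[:, None, :] - Z[None, :, :]
    D = np.sqrt((diff ** 2).sum(axis=2))
    return D * (1.0 + shared_frac)


def _w_statistic(D: np.ndarray, focal_mask: np.ndarray) -> float:
    iu = np.triu_indices(D.shape[0], k=1)
    all_mean = D[iu].mean()
    sub = D[np.ix_(focal_mask, focal_mask)]
    iuf = np.triu_indices(sub.shape[0], k=1)
    focal_mean = sub[iuf].mean()
    if all_mean == 0:
        raise ValueError("all species have identical trait values; w undefined")
    if focal_mean == 0:
        return np.inf
    return float(all_mean / focal_mean)


def wheatsheaf(tree: PhyloTree, trait_matrix: pd.DataFrame, focal_species,
               n_boot: int = 500, seed: int = 0) -> WheatsheafResult:
    """Wheatsheaf convergence index for a focal species set.

    Trait columns are standardized; higher w means the focal species sit
    closer together in phenotype space than the clade at large, after
    penalizing phylogenetic relatedness. The bootstrap p-value is the
    proportion of random same-size focal sets with w at least as large
    ((r+1)/(n_boot+1) correction).
    """
    df = trait_matrix.dropna()
    labels = [l for l in tree.tip_labels if l in set(df.index)]
    sub = tree.prune_to(labels) if set(labels) != set(tree.tip_labels) else tree
    df = df.loc[sub.tip_labels]
    focal = [s for s in focal_species if s in set(sub.tip_labels)]
    if len(focal) < 2 or len(labels) - len(focal) < 2:
        raise ValueError("need >= 2 focal and >= 2 non-focal species with data")
    Z = df.to_numpy(dtype=float)
    sd = Z.std(axis=0, ddof=0)
    if np.any(sd == 0):
        sd = np.where(sd == 0, 1.0, sd)
    Z = (Z - Z.mean(axis=0)) / sd
    C = mrca_depth_matrix(sub)
    shared = C / sub.height
    np.fill_diagonal(shared, 0.0)
    D = _penalized_distances(Z, shared)
    mask = np.array([l in set(focal) for l in sub.tip_labels])
    w_obs = _w_statistic(D, mask)
    rng = np.random.default_rng(seed)
    n = len(sub.tip_labels)
    r = 0
    for _ in range(n_boot):
        idx = rng.choice(n, size=int(mask.sum()), replace=False)
        bmask = np.zeros(n, dtype=bool)
        bmask[idx] = True
        if _w_statistic(D, bmask) >= w_obs:
            r += 1
    p = (r + 1) / (n_boot + 1)
    return WheatsheafResult(w_obs, float(p), n_boot, focal,
                            list(trait_matrix.columns), seed)
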