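"""Continuous-time Markov (Mk) models for a binary character and stochastic
character mapping.

The parity mode (oviparous / viviparous) is modelled as a two-state Markov
chain on the tree. Models differ in their rate constraints: ER (equal rates,
one free rate), SYM (symmetric; identical to ER for a binary character) and
ARD (all rates different, two free rates). Model choice uses the small-sample
Akaike criterion AICc with n = number of tips. Stochastic maps are drawn by
sampling ancestral states from their conditional distributions and then
branch histories conditional on endpoint states by uniformization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import poisson

from .regimes import RegimeMap
from .tree import PhyloTree

__all__ = [
    "MkModel", "MkFit", "StochasticMapSet",
    "mk_likelihood", "fit_mk", "compare_mk", "stochastic_maps", "count_origins",
]

CONSTRAINTS = ("ER", "SYM", "ARD")
RATE_BOUNDS = (1e-8, 1e3)            # per My, optimizer box
MULTISTART_RATES = np.geomspace(1e-4, 10.0, 5)
UNIFORMIZATION_RETRY_CAP = 10_000


# ----------------------------------------------------------------- model
@dataclass
class MkModel:
    """A two-state Markov model with rate matrix Q (rows sum to zero)."""

    states: tuple
    Q: np.ndarray
    constraint: str = "ER"
    root_prior: str = "stationary"    # stationary | flat | fitted

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (2, 2):
            raise ValueError("binary character: Q must be 2x2")
        off = self.Q[~np.eye(2, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(self.Q.sum(axis=1), 0.0, atol=1e-12):
            raise ValueError("Q rows must sum to 0")

    @property
    def k(self) -> int:
        """Number of free rate parameters."""
        return 2 if self.constraint == "ARD" else 1

    def stationary(self) -> np.ndarray:
        q01, q10 = self.Q[0, 1], self.Q[1, 0]
        s = q01 + q10
        if s == 0:
            return np.array([0.5, 0.5])
        return np.array([q10 / s, q01 / s])

    def transition_matrix(self, t: float) -> np.ndarray:
        """Closed-form matrix exponential for a 2-state chain."""
        q01, q10 = self.Q[0, 1], self.Q[1, 0]
        s = q01 + q10
        if s == 0:
            return np.eye(2)
        pi = self.stationary()
        e = math.exp(-s * t)
        P = np.empty((2, 2))
        P[0, 0] = pi[0] + pi[1] * e
        P[0, 1] = pi[1] - pi[1] * e
        P[1, 0] = pi[0] - pi[0] * e
        P[1, 1] = pi[1] + pi[0] * e
        return P


@dataclass
class MkFit:
    model: MkModel
    loglik: float
    k: int
    n: int
    aicc: float
    delta_aicc: float = np.nan
    weight: float = np.nan
    n_starts: int = 0


def aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ------------------------------------------------------------- likelihood
def _states_array(tree: PhyloTree, tip_states) -> np.ndarray:
    """Tip states as 0/1 in tree tip order; accepts dict/Series of labels."""
    if isinstance(tip_states, (dict, pd.Series)):
        vals = [tip_states[l] for l in tree.tip_labels]
    else:
        vals = list(tip_states)
    arr = np.asarray(vals)
    if arr.dtype.kind not in "iub":
        uniq = sorted(set(arr.tolist()))
        if len(uniq) > 2:
            raise ValueError(f"binary character expected, got states {uniq}")
        arr = np.array([uniq.index(v) for v in arr])
    return arr.astype(np.int64)


def _root_weights(prior: str, model: MkModel, partial: np.ndarray) -> np.ndarray:
    if prior == "stationary":
        return model.stationary()
    if prior == "flat":
        return np.array([0.5, 0.5])
    if prior == "fitted":      # FitzJohn-style: weight by the data itself
        s = partial.sum()
        return partial / s if s > 0 else np.array([0.5, 0.5])
    raise ValueError(f"unknown root prior {prior!r}")


def _pruning(tree: PhyloTree, states: np.ndarray, model: MkModel):
    """Post-order conditional likelihoods with log-scaling.

    Returns (partials, scale_log, branch transition matrices).
    """
    n = tree.n_nodes
    L = np.zeros((n, 2))
    P = [None] * n
    scale = 0.0
    is_tip = np.zeros(n, dtype=bool)
    is_tip[tree.tips] = True
    tip_pos = {int(t): k for k, t in enumerate(tree.tips)}
    for u in tree.postorder:
        if is_tip[u]:
            L[u, states[tip_pos[u]]] = 1.0
        else:
            L[u] = 1.0
            for c in tree.children[u]:
                P[c] = model.transition_matrix(float(tree.lengths[c]))
                L[u] *= P[c] @ L[c]
            m = L[u].max()
            if m <= 0:
                return L, -np.inf, P
            L[u] /= m
            scale += math.log(m)
    return L, scale, P


def mk_likelihood(tree: PhyloTree, tip_states, Q, root_prior: str = "stationary") -> float:
    """Log-likelihood of binary tip states under rate matrix Q (pruning)."""
    model = Q if isinstance(Q, MkModel) else MkModel(("0", "1"), Q, root_prior=root_prior)
    states = _states_array(tree, tip_states)
    L, scale, _ = _pruning(tree, states, model)
    if not np.isfinite(scale):
        return -np.inf
    w = _root_weights(root_prior, model, L[tree.root])
    lik = float(w @ L[tree.root])
    if lik <= 0:
        return -np.inf
    return math.log(lik) + scale


# ---------------------------------------------------------------- fitting
def _build_Q(rates: np.ndarray, constraint: str) -> np.ndarray:
    if constraint in ("ER", "SYM"):
        q01 = q10 = rates[0]
    elif constraint == "ARD":
        q01, q10 = rates
    else:
        raise ValueError(f"constraint must be one of {CONSTRAINTS}")
    return np.array([[-q01, q01], [q10, -q10]])


def fit_mk(tree: PhyloTree, tip_states, constraint: str = "ER",
           root_prior: str = "stationary") -> MkFit:
    """Maximum-likelihood Mk fit with multi-start bounded optimization."""
    states = _states_array(tree, tip_states)
    if tree.n_tips < 2:
        raise ValueError("need >= 2 tips")
    n_rates = 2 if constraint == "ARD" else 1

    def nll(log_rates):
        Q = _build_Q(np.exp(log_rates), constraint)
        ll = mk_likelihood(tree, states, Q, root_prior)
        return 1e10 if not np.isfinite(ll) else -ll

    best = None
    bounds = [(math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1]))] * n_rates
    tries = 0
    for r0 in MULTISTART_RATES:
        x0 = np.full(n_rates, math.log(r0))
        try:
            res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
            tries += 1
        except Exception:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e9:
        raise RuntimeError(
            f"Mk optimization failed for {constraint} after {tries} starts")
    rates = np.exp(best.x)
    model = MkModel(("0", "1"), _build_Q(rates, constraint), constraint, root_prior)
    ll = -float(best.fun)
    n = tree.n_tips
    return MkFit(model, ll, model.k, n, aicc(ll, model.k, n), n_starts=tries)


def compare_mk(tree: PhyloTree, tip_states, constraints=CONSTRAINTS,
               root_prior: str = "stationary") -> pd.DataFrame:
    """Fit a set of rate constraints and compare by AICc / Akaike weights."""
    fits = {c: fit_mk(tree, tip_states, c, root_prior) for c in constraints}
    ai = np.array([fits[c].aicc for c in constraints])
    delta = ai - ai.min()
    w = np.exp(-0.5 * delta)
    w /= w.sum()
    rows = []
    for c, d, wt in zip(constraints, delta, w):
        f = fits[c]
        f.delta_aicc, f.weight = float(d), float(wt)
        rows.append({"model": c, "logL": f.loglik, "k": f.k, "AICc": f.aicc,
                     "dAICc": f.delta_aicc, "weight": f.weight,
                     "q01": f.model.Q[0, 1], "q10": f.model.Q[1, 0]})
    df = pd.DataFrame(rows).set_index("model")
    df.attrs["fits"] = fits
    return df


# ------------------------------------------------------- stochastic mapping
@dataclass
class StochasticMapSet:
    maps: list
    Q: np.ndarray
    seed: int
    state_labels: tuple
    counts: pd.DataFrame = field(default=None)

    def __len__(self):
        return len(self.maps)


def _sample_branch_history(rng, Q: np.ndarray, a: int, b: int, t: float):
    """Times and states of changes on a branch conditional on endpoints,
    drawn by uniformization (exact). Returns [(time, new_state), ...]."""
    if t == 0.0:
        if a != b:
            raise RuntimeError("zero-length branch with differing endpoints")
        return []
    omega = float(max(-Q[0, 0], -Q[1, 1]))
    if omega == 0.0:
        if a != b:
            raise RuntimeError("zero rate matrix with differing endpoints")
        return []
    R = np.eye(2) + Q / omega
    model = MkModel(("0", "1"), Q)
    p_ab = model.transition_matrix(t)[a, b]
    if p_ab <= 0:
        raise RuntimeError(f"impossible endpoint pair ({a},{b}) on branch")
    # number of uniformized jumps
    u = rng.random() * p_ab
    acc = 0.0
    Rpow = [np.eye(2)]
    n_jumps = None
    for n in range(UNIFORMIZATION_RETRY_CAP):
        if n > 0:
            Rpow.append(Rpow[-1] @ R)
        term = poisson.pmf(n, omega * t) * Rpow[n][a, b]
        acc += term
        if acc >= u:
            n_jumps = n
            break
    if n_jumps is None:
        raise RuntimeError("uniformization failed to converge on a jump count")
    if n_jumps == 0:
        return []
    # jump-chain states, forward sampling conditioned on the endpoint
    states = [a]
    for j in range(1, n_jumps):
        m = n_jumps - j
        w = np.array([R[states[-1], c] * Rpow[m][c, b] for c in (0, 1)])
        states.append(int(rng.random() * w.sum() > w[0]))
    states.append(b)
    times = np.sort(rng.random(n_jumps)) * t
    history = []
    cur = a
    for j in range(n_jumps):
        nxt = states[j + 1]
        if nxt != cur:                       # drop virtual (self) jumps
            history.append((float(times[j]), nxt))
            cur = nxt
    return history


def stochastic_maps(tree: PhyloTree, tip_states, fit, n_maps: int, seed: int,
                    state_labels=("oviparous", "viviparous"),
                    root_prior: str | None = None) -> StochasticMapSet:
    """Draw stochastic character maps under a fitted (or given) Q.

    Each map samples ancestral node states from their joint conditional
    distribution given the tip data, then fills in branch histories by
    uniformization conditional on the sampled endpoints.
    """
    if isinstance(fit, MkFit):
        model = fit.model
    elif isinstance(fit, MkModel):
        model = fit
    else:
        model = MkModel(("0", "1"), np.asarray(fit, dtype=float))
    if root_prior is None:
        root_prior = model.root_prior
    if not np.all(np.isfinite(model.Q)):
        raise ValueError("Q must be finite")
    states = _states_array(tree, tip_states)
    L, scale, P = _pruning(tree, states, model)
    if not np.isfinite(scale):
        raise ValueError("tip states have zero likelihood under Q")
    rng = np.random.default_rng(seed)
    Q = model.Q
    maps = []
    rows = []
    is_tip = np.zeros(tree.n_nodes, dtype=bool)
    is_tip[tree.tips] = True
    for m in range(n_maps):
        node_state = np.empty(tree.n_nodes, dtype=np.int64)
        w = _root_weights(root_prior, model, L[tree.root]) * L[tree.root]
        node_state[tree.root] = int(rng.random() * w.sum() > w[0])
        for u in tree.preorder:
            if u == tree.root:
                continue
            pa = node_state[tree.parent[u]]
            w = P[u][pa] * L[u]
            node_state[u] = int(rng.random() * w.sum() > w[0])
        histories = {}
        for u in tree.preorder:
            if u == tree.root:
                continue
            hist = _sample_branch_history(
                rng, Q, int(node_state[tree.parent[u]]), int(node_state[u]),
                float(tree.lengths[u]))
            histories[u] = [(tt, state_labels[s]) for tt, s in hist]
        rmap = RegimeMap.from_histories(tree, state_labels[node_state[tree.root]],
                                        histories)
        maps.append(rmap)
        cts = rmap.transition_counts()
        rows.append({
            "map": m,
            "forward": cts.get((state_labels[0], state_labels[1]), 0),
            "reverse": cts.get((state_labels[1], state_labels[0]), 0),
        })
    counts = pd.DataFrame(rows).set_index("map")
    return StochasticMapSet(maps, Q.copy(), seed, tuple(state_labels), counts)


@dataclass
class OriginCounts:
    origins: np.ndarray        # per-map count of ancestral -> derived shifts
    reversals: np.ndarray
    modal: int
    modal_freq: float

    def summary(self) -> pd.Series:
        return pd.Series({
            "modal_origins": self.modal,
            "modal_freq": self.modal_freq,
            "mean_origins": float(self.origins.mean()),
            "mean_reversals": float(self.reversals.mean()),
        })


def count_origins(mapset: StochasticMapSet, derived_state: str) -> OriginCounts:
    """Per-map counts of transitions into `derived_state`, and the modal count."""
    if not mapset.maps:
        raise ValueError("empty map set")
    origins, reversals = [], []
    for rmap in mapset.maps:
        cts = rmap.transition_counts()
        fwd = sum(v for (a, b), v in cts.items() if b == derived_state)
        rev = sum(v for (a, b), v in cts.items() if a == derived_state)
        origins.append(fwd)
        reversals.append(rev)
    origins = np.array(origins)
    reversals = np.array(reversals)
    vals, cts = np.unique(origins, return_counts=True)
    i = int(np.argmax(cts))
    return OriginCounts(origins, reversals, int(vals[i]), float(cts[i] / origins.size))
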