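import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from phryno import ou, simulate
from phryno.regimes import RegimeMap
from phryno.tree import mrca_depth_matrix, tree_from_newick


def _two_regime_map():
    tree = tree_from_newick("((A:1,B:1):1,C:2);")
    lab = {tree.labels[int(t)]: int(t) for t in tree.tips}
    inner = [u for u in range(tree.n_nodes)
             if u != tree.root and tree.children[u]][0]
    segs = [[] for _ in range(tree.n_nodes)]
    segs[inner] = [("ovi", 1.0)]
    segs[lab["A"]] = [("ovi", 0.25), ("viv", 0.75)]
    segs[lab["B"]] = [("ovi", 1.0)]
    segs[lab["C"]] = [("ovi", 2.0)]
    return RegimeMap(tree, segs, "ovi")


def test_design_weights_single_regime(cherry):
    m = RegimeMap.single_regime(cherry, "ovi")
    W, regimes = ou.oum_design(m, alpha=0.7)
    assert regimes == ["ovi"]
    np.testing.assert_allclose(W, 1.0)


def test_design_weights_alpha_infinity_limit():
    m = _two_regime_map()
    W, regimes = ou.oum_design(m, alpha=200.0)
    i = m.tree.tip_index("A")
    np.testing.assert_allclose(W[i, regimes.index("viv")], 1.0, atol=1e-12)
    assert np.allclose(W.sum(axis=1), 1.0)


def test_design_weights_match_ode_integration():
    """E[X_tip] from the weights equals numerical integration of
    dE/dt = alpha (theta(t) - E) along each root-to-tip path."""
    m = _two_regime_map()
    alpha = 0.5
    theta = {"ovi": 3.0, "viv": -2.0}
    W, regimes = ou.oum_design(m, alpha)
    th = np.array([theta[r] for r in regimes])
    for lab in m.tree.tip_labels:
        segs = m.path_segments(lab)

        def rhs(t, yv):
            reg = next(r for t0, t1, r in segs if t0 - 1e-12 <= t <= t1 + 1e-12)
            return alpha * (theta[reg] - yv)

        sol = solve_ivp(rhs, (0.0, segs[-1][1]), [theta[m.root_state]],
                        rtol=1e-10, atol=1e-12, max_step=0.05)
        want = sol.y[0, -1]
        got = float(W[m.tree.tip_index(lab)] @ th)
        assert got == pytest.approx(want, abs=1e-6)


def test_design_requires_positive_alpha():
    with pytest.raises(ValueError, match="alpha"):
        ou.oum_design(_two_regime_map(), 0.0)


def test_ou_covariance_limits(three_tip):
    # alpha -> 0: entries approach sigma2 x shared path length (BM)
    V = ou.ou_covariance(three_tip, alpha=1e-6, sigma2=1.0).matrix
    np.testing.assert_allclose(V, mrca_depth_matrix(three_tip), rtol=1e-4)
    # root divergence, large alpha T: covariance 0, variance sigma2/(2 alpha)
    cherry_deep = tree_from_newick("(A:50,B:50);")
    V2 = ou.ou_covariance(cherry_deep, alpha=1.0, sigma2=2.0).matrix
    assert V2[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert V2[0, 0] == pytest.approx(1.0, rel=1e-10)


def test_ou_covariance_rejects_nonultrametric():
    with pytest.raises(ValueError, match="ultrametric"):
        ou.ou_covariance(tree_from_newick("(A:1,B:2);"), 0.5, 1.0)


def test_ou_covariance_matches_simulation():
    tree = simulate.simulate_tree(10, 0.1, 0.02, seed=9, height=20.0)
    alpha, sigma2 = 0.2, 1.5
    m = RegimeMap.single_regime(tree, "one")
    n_rep = 20_000
    X = np.empty((n_rep, tree.n_tips))
    for r in range(n_rep):
        X[r] = simulate.simulate_ou(m, alpha, sigma2, {"one": 0.0},
                                    x0=None, seed=r).to_numpy()
    emp = np.cov(X, rowvar=False)
    want = ou.ou_covariance(tree, alpha, sigma2).matrix
    # Monte-Carlo tolerance ~ 3 / sqrt(n_rep) on correlations of scale ~vy
    vy = sigma2 / (2 * alpha)
    np.testing.assert_allclose(emp, want, atol=4 * vy / math.sqrt(n_rep) * 10)


def test_oum_with_single_regime_painting_equals_ou1(study):
    tb = study.traits["Tb"]
    uni = RegimeMap.single_regime(study.tree, "all")
    f_oum = ou.fit_continuous(uni, tb, "OUM")
    f_ou1 = ou.fit_continuous(uni, tb, "OU1")
    assert f_oum.loglik == pytest.approx(f_ou1.loglik, abs=1e-6)
    assert list(f_oum.theta.values())[0] == pytest.approx(
        list(f_ou1.theta.values())[0], abs=1e-4)


def test_nesting_order_of_loglikelihoods(study, rng):
    # BM-simulated data: OU1 contains BM in its closure, OUM contains OU1
    y = simulate.simulate_bm(study.tree, 1.0, 0.0, seed=33)
    f_bm = ou.fit_continuous(study.tree, y, "BM1")
    f_ou1 = ou.fit_continuous(study.tree, y, "OU1")
    f_oum = ou.fit_continuous(study.regime_map, y, "OUM")
    assert f_ou1.loglik >= f_bm.loglik - 1e-6
    assert f_oum.loglik >= f_ou1.loglik - 1e-6


def test_fit_is_affine_equivariant(study):
    tb = study.traits["Tb"]
    f1 = ou.fit_continuous(study.regime_map, tb, "OUM")
    f2 = ou.fit_continuous(study.regime_map, 2.0 * tb + 5.0, "OUM")
    assert f2.alpha == pytest.approx(f1.alpha, rel=1e-3)
    assert f2.sigma2 == pytest.approx(4.0 * f1.sigma2, rel=1e-3)
    for r in f1.theta:
        assert f2.theta[r] == pytest.approx(2.0 * f1.theta[r] + 5.0, rel=1e-3)


def test_half_life_values():
    assert ou.half_life(math.log(2)) == pytest.approx(1.0)
    assert ou.half_life(0.0) == math.inf
    assert ou.half_life(0.08) == pytest.approx(8.664, abs=1e-3)
    with pytest.raises(ValueError):
        ou.half_life(-0.1)


def test_fold_change():
    assert ou.fold_change(3.0, 3.0) == 1.0
    assert ou.fold_change(1.5, 0.5, log10_scale=True) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        ou.fold_change(-1.0, 2.0)


def test_fit_over_maps_deterministic(study, study_maps):
    tb = study.traits["Tb"]
    maps = [study_maps.maps[0]] * 5
    res = ou.fit_over_maps(maps, tb, models=("OUM",))
    thetas = res.records["theta_viviparous"]
    assert thetas.nunique() == 1
    assert res.n_maps == 5 and res.n_excluded == 0


def test_oum_preferred_on_oum_data(study, study_maps):
    res = ou.fit_over_maps(study_maps.maps[:10], study.traits["Tb"])
    support = res.model_support()
    assert support.get("OUM", 0.0) > 0.9


def test_type1_smoke():
    tree = simulate.simulate_tree(6, 0.1, 0.0, seed=1, height=10.0)
    res = ou.type1_error_experiment(tree, n_sims=1, seed=0)
    assert res.false_positive_rate in (0.0, 1.0)


def test_alpha_boundary_flagged():
    # anti-correlated sister pairs leave no resolvable phylogenetic signal:
    # the alpha profile is flat to the upper bound, flagged "alpha = inf"
    tree = tree_from_newick("((A:1,B:1):9,((C:1,D:1):4,(E:1,F:1):4):5);")
    y = pd.Series({"A": 5, "B": -5, "C": 5, "D": -5, "E": 5, "F": -5.0})
    f = ou.fit_continuous(tree, y, "OU1")
    assert f.alpha_at_bound
    # a trait with clear mean-reversion at finite rate is not flagged
    tb_map = RegimeMap.single_regime(simulate.simulate_tree(
        60, 0.1, 0.02, seed=2, height=65.0), "x")
    y2 = simulate.simulate_ou(tb_map, 0.1, 1.0, {"x": 0.0}, seed=3)
    f2 = ou.fit_continuous(tb_map.tree, y2, "OU1")
    assert not f2.alpha_at_bound
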