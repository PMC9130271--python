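import math

import numpy as np
import pandas as pd
import pytest

from phryno import ecophys, ou, simulate
from phryno.regimes import RegimeMap
from phryno.tree import check_ultrametric, tree_from_newick


class TestTreeSimulation:
    def test_two_tip_cherry_of_requested_height(self):
        t = simulate.simulate_tree(2, 0.1, 0.0, seed=1, height=10.0)
        assert t.n_tips == 2
        assert t.height == pytest.approx(10.0)
        np.testing.assert_allclose(t.tip_depths(), 10.0)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_output_is_ultrametric(self, seed):
        t = simulate.simulate_tree(40, 0.08, 0.03, seed=seed, height=65.0)
        assert check_ultrametric(t).is_ultrametric
        assert t.lengths[t.tips].min() > 0  # no zero-length stopping artifact

    def test_yule_epoch_durations_match_expectation(self):
        """Pure-birth oracle: while k lineages exist the waiting time to the
        next split is Exp(k b), so mean epoch durations are 1/(k b)."""
        b, n, reps = 1.0, 10, 200
        sums = np.zeros(n - 2)
        for seed in range(reps):
            t = simulate.simulate_tree(n, b, 0.0, seed=seed)
            depths = np.sort([t.depths[u] for u in range(t.n_nodes)
                              if t.children[u]])
            # epoch while k lineages runs between the (k-1)-th and k-th split
            sums += np.diff(depths)
        mean_epochs = sums / reps
        for i, k in enumerate(range(2, n - 1)):
            want = 1.0 / (k * b)
            se = want / math.sqrt(reps)   # Exp(k b) has sd = mean
            assert mean_epochs[i] == pytest.approx(want, abs=4 * se)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_tree(10, 0.05, 0.05, seed=1)


class TestDiscreteSimulation:
    def test_zero_rate_inherits_root_state(self, midsize_tree):
        tips, rmap = simulate.simulate_discrete(midsize_tree, np.zeros((2, 2)),
                                                seed=1)
        assert (tips == "oviparous").all()
        assert rmap.n_transitions() == 0

    def test_one_way_change_probability_closed_form(self):
        r, t, reps = 0.3, 2.0, 3000
        tree = tree_from_newick(f"(A:{t},B:{t});")
        Q = np.array([[-r, r], [0.0, 0.0]])
        hits = 0
        for s in range(reps):
            tips, _ = simulate.simulate_discrete(tree, Q, seed=s)
            hits += tips["A"] == "viviparous"
        want = 1 - math.exp(-r * t)
        se = math.sqrt(want * (1 - want) / reps)
        assert hits / reps == pytest.approx(want, abs=3 * se)

    def test_mean_change_count_matches_rate_times_length(self):
        # unconditioned forward histories: E[#changes] = rate x total length
        tree = simulate.simulate_tree(30, 0.1, 0.02, seed=6, height=30.0)
        q = 0.01
        Q = np.array([[-q, q], [q, -q]])
        total = tree.lengths.sum()
        counts = [simulate.simulate_discrete(tree, Q, seed=s)[1].n_transitions()
                  for s in range(300)]
        want = q * total
        se = math.sqrt(want / 300)  # Poisson-ish
        assert np.mean(counts) == pytest.approx(want, abs=3 * se)


class TestOUSimulation:
    def test_bm_limit_variance_grows_linearly(self):
        tree = tree_from_newick("(A:4,B:4);")
        m = RegimeMap.single_regime(tree, "x")
        vals = np.array([simulate.simulate_ou(m, 0.0, 2.0, {"x": 0.0},
                                              x0=0.0, seed=s)["A"]
                         for s in range(4000)])
        assert vals.var() == pytest.approx(8.0, rel=0.1)

    def test_stationary_moments_on_long_branch(self):
        tree = tree_from_newick("(A:200,B:200);")
        m = RegimeMap.single_regime(tree, "x")
        alpha, sig2, theta = 0.5, 3.0, 7.0
        vals = np.array([simulate.simulate_ou(m, alpha, sig2, {"x": theta},
                                              x0=0.0, seed=s)["A"]
                         for s in range(4000)])
        assert vals.mean() == pytest.approx(theta, abs=0.1)
        assert vals.var() == pytest.approx(sig2 / (2 * alpha), rel=0.1)

    def test_tip_expectations_match_design_weights(self):
        tree = tree_from_newick("((A:1,B:1):1,C:2);")
        lab = {tree.labels[int(t)]: int(t) for t in tree.tips}
        inner = [u for u in range(tree.n_nodes)
                 if u != tree.root and tree.children[u]][0]
        segs = [[] for _ in range(tree.n_nodes)]
        segs[inner] = [("a", 1.0)]
        segs[lab["A"]] = [("a", 0.3), ("b", 0.7)]
        segs[lab["B"]] = [("a", 1.0)]
        segs[lab["C"]] = [("a", 0.5), ("b", 1.5)]
        m = RegimeMap(tree, segs, "a")
        alpha, theta = 0.8, {"a": 0.0, "b": 10.0}
        X = np.array([simulate.simulate_ou(m, alpha, 1.0, theta, seed=s)
                      .to_numpy() for s in range(3000)])
        W, regimes = ou.oum_design(m, alpha)
        want = W @ np.array([theta[r] for r in regimes])
        se = X.std(axis=0) / math.sqrt(len(X))
        np.testing.assert_array_less(np.abs(X.mean(axis=0) - want), 4 * se + 1e-9)


class TestStudyDataset:
    def test_complete_table_without_missingness(self, study):
        tr = study.traits
        for col in ("parity", "Tb", "Tpref", "CTmin", "CTmax", "SVL", "mass",
                    "clutch_size", "clutches_per_year", "offspring_mass",
                    "bio1", "bio10", "bio11", "E", "I", "B", "Pr",
                    "annual_fecundity"):
            assert col in tr.columns
            assert tr[col].notna().all(), col

    def test_planted_origins_and_no_reversals(self, study):
        cts = study.regime_map.transition_counts()
        assert cts.get(("oviparous", "viviparous"), 0) == 5
        assert ("viviparous", "oviparous") not in cts

    def test_allometry_recovered(self, study):
        fit = ecophys.fit_allometry(study.traits["SVL"], study.traits["mass"])
        assert fit.slope == pytest.approx(study.config.allometry_slope, abs=0.1)

    def test_effectiveness_column_recomputable_from_observations(self, study):
        obs, tr = study.observations, study.traits
        for sp in tr.index[:15]:
            grp = obs[obs["species"] == sp]
            s = ecophys.ThermoregSample(
                grp.loc[grp["kind"] == "Tb", "value"].to_numpy(),
                grp.loc[grp["kind"] == "Te", "value"].to_numpy(),
                tr.loc[sp, "Tset25"], tr.loc[sp, "Tset75"])
            assert s.effectiveness() == tr.loc[sp, "E"]

    def test_mean_effectiveness_near_configured_level(self, study):
        assert study.traits["E"].mean() == pytest.approx(
            study.config.thermoreg_precision, abs=0.1)

    def test_bit_reproducible_under_fixed_seed(self):
        cfg = simulate.SynthConfig(seed=42, n_tips=40)
        d1 = simulate.generate_study_dataset(cfg)
        d2 = simulate.generate_study_dataset(simulate.SynthConfig(seed=42, n_tips=40))
        pd.testing.assert_frame_equal(d1.traits, d2.traits)
        pd.testing.assert_frame_equal(d1.observations, d2.observations)
        np.testing.assert_array_equal(d1.tree.lengths, d2.tree.lengths)
        d3 = simulate.generate_study_dataset(simulate.SynthConfig(seed=43, n_tips=40))
        assert not d3.traits["Tb"].equals(d1.traits["Tb"])

    def test_missingness_applied(self):
        cfg = simulate.SynthConfig(seed=3, n_tips=40,
                                   missingness={"CTmax": 0.3})
        ds = simulate.generate_study_dataset(cfg)
        frac = ds.traits["CTmax"].isna().mean()
        assert 0.1 < frac < 0.5
        with pytest.raises(ValueError):
            simulate.SynthConfig(missingness={"Tb": 1.2})
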