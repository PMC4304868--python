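"""Squared-change parsimony, permutation test, Pagel's lambda, bounded BM."""

import math

import dendropy
import numpy as np
import pytest
from scipy import optimize, stats

from copyvar import phylo_signal as ps
from copyvar import synth


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


def trait(newick_str, values):
    return ps.PhyloTrait(newick(newick_str), dict(values))


class TestSCP:
    def test_two_tip_closed_form(self):
        pt = trait("(a:1,b:1);", {"a": 2.0, "b": 6.0})
        res = ps.scp_ancestral_states(pt)
        assert res.root_state == pytest.approx(4.0)  # midpoint
        assert res.scp_length == pytest.approx(8.0)  # (a-b)^2 / 2

    def test_constant_tips_zero_length(self):
        pt = trait("((a:1,b:1):1,(c:1,d:1):1);", {t: 5.0 for t in "abcd"})
        res = ps.scp_ancestral_states(pt)
        assert res.scp_length == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(5.0) for v in res.node_states.values())

    def test_three_tip_star_minimizes_at_mean(self):
        pt = trait("(a:1,b:1,c:1);", {"a": 0.0, "b": 0.0, "c": 3.0})
        res = ps.scp_ancestral_states(pt)
        assert res.root_state == pytest.approx(1.0)
        assert res.scp_length == pytest.approx(6.0)

    @pytest.mark.parametrize("weighted", [False, True])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_numeric_minimizer_on_random_trees(self, seed, weighted):
        """Exact linear-system solution equals direct numeric minimization of
        the quadratic objective on random trees of up to 8 tips."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        tree = synth.random_bifurcating_tree(n, rng)
        values = {f"t{i}": float(rng.normal(10, 5)) for i in range(1, n + 1)}
        pt = ps.PhyloTrait(tree, values)
        res = ps.scp_ancestral_states(pt, weighted=weighted)
        order = pt.tip_labels
        edges, internals = ps._index_tree(pt.tree, order)
        t = pt.value_vector(order)
        n_int = len(internals)

        def objective(x):
            full = np.concatenate([t, x])
            s = 0.0
            for u, v, length in edges:
                w = 1.0 / length if weighted else 1.0
                s += w * (full[u] - full[v]) ** 2
            return s

        x0 = np.full(n_int, t.mean())
        opt = optimize.minimize(objective, x0, method="BFGS", options={"gtol": 1e-12})
        assert res.scp_length == pytest.approx(opt.fun, abs=1e-6)
        got = np.array([res.node_states[nd] for nd in internals])
        assert np.allclose(got, opt.x, atol=1e-4)

    def test_invariant_under_value_permuting_relabel(self):
        """Swapping the labels of tips that carry identical values leaves the
        SCP length unchanged."""
        pt1 = trait("((a:1,b:2):1,(c:1,d:2):3);", {"a": 4, "b": 4, "c": 9, "d": 1})
        pt2 = trait("((b:1,a:2):1,(c:1,d:2):3);", {"a": 4, "b": 4, "c": 9, "d": 1})
        r1 = ps.scp_ancestral_states(pt1)
        r2 = ps.scp_ancestral_states(pt2)
        assert r1.scp_length == pytest.approx(r2.scp_length)

    def test_weighted_zero_branch_rejected(self):
        pt = trait("((a:1,b:1):0,c:1);", {"a": 1, "b": 2, "c": 3})
        with pytest.raises(ValueError, match="collapse"):
            ps.scp_ancestral_states(pt, weighted=True)


class TestPermutationTest:
    def test_constant_values_degenerate(self):
        pt = trait("((a:1,b:1):1,(c:1,d:1):1);", {t: 3.0 for t in "abcd"})
        assert ps.permutation_signal_test(pt, n_perm=200, seed=0) == 0.0

    def test_strong_signal_detected(self):
        """Values sorted onto the two halves of a balanced 16-tip tree give a
        small permutation p in nearly all seeds."""
        tips = [f"t{i}" for i in range(16)]
        half = "(" + ",".join(f"{t}:1" for t in tips[:8]) + "):1"
        other = "(" + ",".join(f"{t}:1" for t in tips[8:]) + "):1"
        tree_str = f"({half},{other});"
        values = {t: (1.0 + 0.01 * i if i < 8 else 10.0 + 0.01 * i) for i, t in enumerate(tips)}
        hits = 0
        for seed in range(20):
            p = ps.permutation_signal_test(trait(tree_str, values), n_perm=2000, seed=seed)
            hits += p < 0.05
        assert hits >= 19

    def test_null_p_values_approximately_uniform(self):
        """With i.i.d. tip values the permutation p-value is approximately
        uniform on [0, 1] (KS calibration check)."""
        rng = np.random.default_rng(42)
        tree = synth.random_bifurcating_tree(16, rng)
        labels = [f"t{i}" for i in range(1, 17)]
        pvals = []
        for rep in range(500):
            values = dict(zip(labels, rng.normal(0, 1, 16)))
            pt = ps.PhyloTrait(tree, values)
            pvals.append(
                ps.permutation_signal_test(pt, n_perm=400, seed=int(rng.integers(2**31)))
            )
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_too_few_tips_rejected(self):
        pt = trait("(a:1,b:1);", {"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError):
            ps.permutation_signal_test(pt, n_perm=10, seed=0)


class TestLambdaTransform:
    def cherry(self):
        return newick("((a:1,b:1):1,c:2);")

    def test_identity_at_lambda_one(self):
        tree = self.cherry()
        V0 = ps.tree_vcv(tree, ["a", "b", "c"])
        V1 = ps.tree_vcv(ps.lambda_transform(tree, 1.0), ["a", "b", "c"])
        assert np.allclose(V0, V1)

    def test_star_at_lambda_zero(self):
        V = ps.tree_vcv(ps.lambda_transform(self.cherry(), 0.0), ["a", "b", "c"])
        assert np.allclose(V - np.diag(np.diag(V)), 0.0)
        assert np.allclose(np.diag(V), [2.0, 2.0, 2.0])

    def test_half_lambda_scales_shared_depth(self):
        V = ps.tree_vcv(ps.lambda_transform(self.cherry(), 0.5), ["a", "b", "c"])
        assert V[0, 1] == pytest.approx(0.5)  # shared depth 1 scaled by 0.5
        assert V[0, 0] == pytest.approx(2.0)  # tip depths preserved

    def test_matches_covariance_form(self):
        tree = self.cherry()
        order = ["a", "b", "c"]
        V = ps.tree_vcv(tree, order)
        for lam in (0.0, 0.3, 0.8, 1.0):
            direct = ps.lambda_vcv(V, lam)
            via_tree = ps.tree_vcv(ps.lambda_transform(tree, lam), order)
            assert np.allclose(direct, via_tree)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ps.lambda_transform(self.cherry(), 1.5)


class TestFitLambda:
    def test_recovery_near_one(self):
        """Traits simulated under pure Brownian motion yield lambda_hat near 1
        on average (200 tips, many replicates)."""
        rng = np.random.default_rng(7)
        hats = []
        for rep in range(100):
            tree = synth.random_bifurcating_tree(200, rng)
            sims, labels = ps.simulate_bm_bounded(
                tree, 1.0, 1e6, n_sims=1, seed=int(rng.integers(2**31))
            )
            pt = ps.PhyloTrait(tree, dict(zip(labels, sims[0])))
            hats.append(ps.fit_lambda(pt).lambda_hat)
        assert abs(np.mean(hats) - 1.0) < 0.05

    def test_independent_traits_give_lambda_near_zero(self):
        rng = np.random.default_rng(8)
        hats = []
        for rep in range(30):
            tree = synth.random_bifurcating_tree(100, rng)
            labels = sorted(f"t{i}" for i in range(1, 101))
            pt = ps.PhyloTrait(tree, dict(zip(labels, rng.normal(0, 1, 100))))
            hats.append(ps.fit_lambda(pt).lambda_hat)
        assert np.mean(hats) < 0.15

    def test_nesting_holds(self):
        rng = np.random.default_rng(9)
        tree = synth.random_bifurcating_tree(30, rng)
        labels = sorted(f"t{i}" for i in range(1, 31))
        pt = ps.PhyloTrait(tree, dict(zip(labels, rng.normal(5, 2, 30))))
        fit = ps.fit_lambda(pt)
        assert fit.logL_lambda >= fit.logL_zero - 1e-9


class TestLRT:
    def test_published_likelihood_pairs(self):
        stat, p = ps.lrt_lambda(-594.192, -597.863)
        assert stat == pytest.approx(7.342, abs=1e-9)
        assert p == pytest.approx(0.0067, abs=5e-5)
        stat, p = ps.lrt_lambda(-587.547, -590.765)
        assert p == pytest.approx(0.0112, abs=5e-5)

    def test_equal_likelihoods(self):
        stat, p = ps.lrt_lambda(-10.0, -10.0)
        assert stat == 0.0
        assert p == 1.0

    def test_inverted_likelihoods_rejected(self):
        with pytest.raises(ValueError):
            ps.lrt_lambda(-11.0, -10.0)


class TestFitBM:
    def test_constant_traits(self):
        pt = trait("((a:1,b:1):1,c:2);", {"a": 4.0, "b": 4.0, "c": 4.0})
        fit = ps.fit_bm(pt, n_starts=5, seed=0)
        assert fit.sigma2_hat == 0.0
        assert fit.root_hat == pytest.approx(4.0)

    def test_rate_recovery(self):
        """Mean ML rate over replicates is within 10% of the simulated rate."""
        rng = np.random.default_rng(10)
        s2 = []
        for rep in range(100):
            tree = synth.random_bifurcating_tree(200, rng)
            sims, labels = ps.simulate_bm_bounded(
                tree, 2.0, 1e6, n_sims=1, seed=int(rng.integers(2**31))
            )
            pt = ps.PhyloTrait(tree, dict(zip(labels, sims[0])))
            s2.append(ps.fit_bm(pt, n_starts=3, seed=rep).sigma2_hat)
        assert abs(np.mean(s2) - 2.0) / 2.0 < 0.10

    def test_never_worse_than_analytic_start(self):
        rng = np.random.default_rng(11)
        tree = synth.random_bifurcating_tree(20, rng)
        labels = sorted(f"t{i}" for i in range(1, 21))
        pt = ps.PhyloTrait(tree, dict(zip(labels, rng.normal(10, 3, 20))))
        V = ps.tree_vcv(pt.tree, labels)
        t = pt.value_vector(labels)
        gls_ll, _, _ = ps._bm_profile_loglik(V, t)
        fit = ps.fit_bm(pt, n_starts=20, seed=1)
        assert fit.logL >= gls_ll - 1e-9


class TestSimulateBMBounded:
    def test_zero_rate_constant(self):
        tree = newick("((a:1,b:1):1,c:2);")
        sims, labels = ps.simulate_bm_bounded(tree, 0.0, 7.0, n_sims=50, seed=0)
        assert np.all(sims == 7.0)

    def test_all_values_respect_lower_bound(self):
        tree = newick("((a:5,b:5):5,c:10);")
        sims, _ = ps.simulate_bm_bounded(tree, 4.0, 0.5, n_sims=2000, seed=1)
        assert np.all(sims >= 0.0)

    def test_variance_matches_closed_form_far_from_bound(self):
        tree = newick("((a:1,b:1):1,c:2);")
        sims, labels = ps.simulate_bm_bounded(tree, 3.0, 1e5, n_sims=8000, seed=2)
        for j, lab in enumerate(labels):
            var = sims[:, j].var()
            se = 3.0 * 2.0 * math.sqrt(2 / 8000)
            assert abs(var - 3.0 * 2.0) < 4 * se  # depth 2 for every tip

    def test_deterministic(self):
        tree = newick("((a:1,b:1):1,c:2);")
        a, _ = ps.simulate_bm_bounded(tree, 1.0, 5.0, n_sims=10, seed=3)
        b, _ = ps.simulate_bm_bounded(tree, 1.0, 5.0, n_sims=10, seed=3)
        assert np.array_equal(a, b)

    def test_root_outside_bounds_rejected(self):
        tree = newick("(a:1,b:1);")
        with pytest.raises(ValueError):
            ps.simulate_bm_bounded(tree, 1.0, -5.0, n_sims=1, seed=0)


class TestCladeExtremeness:
    def test_bonferroni_arithmetic(self):
        assert int(math.floor(10_000 * 0.05 / 53)) == 9
        assert int(math.floor(100 * 0.05 / 1)) == 5

    def test_bonferroni_from_tree(self):
        rng = np.random.default_rng(12)
        tree = synth.random_bifurcating_tree(54, rng)  # 53 internal nodes
        labels = sorted(f"t{i}" for i in range(1, 55))
        values = dict(zip(labels, rng.uniform(10, 20, 54)))
        pt = ps.PhyloTrait(tree, values)
        sims, sl = ps.simulate_bm_bounded(tree, 1.0, 15.0, n_sims=10_000, seed=1)
        res = ps.clade_extremeness(pt, sims, sl, alpha=0.05)
        assert res.n_clades == 53
        assert res.bonferroni_critical == 9

    def test_strict_inequality(self):
        """Simulations exactly equal to the observed state never count."""
        tree = newick("((a:1,b:1):1,(c:1,d:1):1);")
        pt = ps.PhyloTrait(tree, {"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        sims = np.ones((100, 4))
        res = ps.clade_extremeness(pt, sims, ["a", "b", "c", "d"])
        assert np.all(res.n_more_extreme == 0)

    def test_extreme_clade_flagged(self):
        """A clade whose tips sit far above the BM expectation accumulates
        almost no more-extreme simulations."""
        tree = newick("((a:1,b:1):1,(c:1,d:1):1);")
        pt = ps.PhyloTrait(tree, {"a": 100.0, "b": 110.0, "c": 1.0, "d": 2.0})
        sims, sl = ps.simulate_bm_bounded(tree, 1.0, 5.0, n_sims=1000, seed=4)
        res = ps.clade_extremeness(pt, sims, sl)
        idx = [i for i, clade in enumerate(res.clades) if clade == ("a", "b")]
        assert len(idx) == 1
        assert res.direction[idx[0]] == "high"
        assert res.n_more_extreme[idx[0]] == 0

    def test_tip_order_mismatch_rejected(self):
        tree = newick("((a:1,b:1):1,c:2);")
        pt = ps.PhyloTrait(tree, {"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError):
            ps.clade_extremeness(pt, np.zeros((5, 3)), ["c", "b", "a"])


class TestPrepareTips:
    def test_two_samples_one_tip_averaged(self):
        tree = newick("((jal:1,x:1):1,y:2);")
        pt = ps.prepare_tips(tree, [("jal", 140.0), ("jal", 165.0), ("x", 5.0), ("y", 7.0)])
        assert pt.values["jal"] == pytest.approx(152.5)

    def test_sample_not_in_tree_dropped(self):
        tree = newick("(a:1,b:1);")
        pt = ps.prepare_tips(tree, [("a", 1.0), ("b", 2.0), ("ghost", 99.0)])
        assert set(pt.values) == {"a", "b"}

    def test_zero_distance_tips_collapsed(self):
        tree = newick("((asp1:0,asp2:0):1,(x:1,y:1):1);")
        pt = ps.prepare_tips(
            tree,
            [("asp1", 342.0), ("asp1", 391.0), ("asp2", 474.0), ("asp2", 347.0),
             ("x", 10.0), ("y", 20.0)],
        )
        assert "asp2" not in pt.values
        assert pt.values["asp1"] == pytest.approx((342 + 391 + 474 + 347) / 4)
        assert len(list(pt.tree.leaf_node_iter())) == 3

    def test_no_overlap_rejected(self):
        tree = newick("(a:1,b:1);")
        with pytest.raises(ValueError):
            ps.prepare_tips(tree, [("q", 1.0)])
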