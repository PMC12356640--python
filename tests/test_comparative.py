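"""BM covariance, Pagel's lambda, ancestral states, phylomorphospace, ANOVA."""

import numpy as np
import pytest

import limbshape as ls
from limbshape.trees import read_newick
from limbshape.comparative import (ComparativeError, simulate_bm_tips,
                                   _lambda_loglik)


def _random_calibrated_tree(seed, n=8):
    return ls.birth_death_tree(n, 0.2, 0.05, seed=seed, depth=20)


class TestBMCovariance:
    def test_two_tip_root_split(self):
        tree = read_newick("(A:7,B:7);")
        for lam in (0.0, 0.5, 1.0):
            C = ls.bm_covariance(tree, lam).C
            np.testing.assert_allclose(C, np.diag([7.0, 7.0]))

    def test_lambda_zero_diagonal(self):
        tree = _random_calibrated_tree(1)
        C = ls.bm_covariance(tree, 0.0).C
        np.testing.assert_allclose(C, np.diag(np.diag(C)))

    def test_matches_path_walk_oracle(self):
        for seed in range(30):
            tree = _random_calibrated_tree(seed, n=int(5 + seed % 6))
            C = ls.bm_covariance(tree).C
            depths = tree.depths()
            anc = {}
            for node in tree.preorder():
                anc[node.id] = (anc[node.parent.id] | {node.parent.id}) \
                    if node.parent else set()
            tips = tree.tips
            for i, a in enumerate(tips):
                for j, b in enumerate(tips):
                    shared = (anc[a.id] | {a.id}) & (anc[b.id] | {b.id})
                    expect = max(depths[s] for s in shared)
                    assert C[i, j] == pytest.approx(expect, abs=1e-10)

    def test_ultrametric_constant_diagonal(self):
        tree = read_newick("((A:5,B:5):5,(C:3,D:3):7);")
        C = ls.bm_covariance(tree).C
        np.testing.assert_allclose(np.diag(C), 10.0)

    def test_lambda_out_of_range(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(ComparativeError):
            ls.bm_covariance(tree, 1.5)


class TestFitLambda:
    def test_profile_optimality(self):
        # the fitted maximum dominates a lambda grid on every fixture
        for seed in range(5):
            tree = _random_calibrated_tree(seed, n=16)
            vals = ls.simulate_traits(tree, 0.1, lambda_true=0.7,
                                      seed=100 + seed)
            x = np.array([vals[t.id] for t in tree.tips])
            fit = ls.fit_lambda(tree, x, n_sim=0)
            C = ls.bm_covariance(tree).C
            for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
                assert fit.loglik_at_hat >= _lambda_loglik(lam, C, x) - 1e-6

    def test_star_tree_unidentifiable(self):
        tree = read_newick("(A:5,B:5,C:5,D:5,E:5);")
        x = np.array([1.0, 2.0, 0.5, -1.0, 0.3])
        fit = ls.fit_lambda(tree, x, n_sim=0)
        assert not fit.identifiable

    def test_zero_variance_rejected(self):
        tree = _random_calibrated_tree(2, n=6)
        with pytest.raises(ComparativeError, match="undefined"):
            ls.fit_lambda(tree, np.ones(6), n_sim=0)

    def test_bm_recovery_small(self):
        # mean lambda_hat near 1 under pure BM (small smoke version of the
        # full calibration in the acceptance suite)
        hats = []
        for seed in range(20):
            tree = ls.birth_death_tree(64, 0.12, 0.06, seed=seed, depth=80)
            vals = ls.simulate_traits(tree, 0.05, lambda_true=1.0,
                                      seed=300 + seed)
            x = np.array([vals[t.id] for t in tree.tips])
            hats.append(ls.fit_lambda(tree, x, n_sim=0).lambda_hat)
        assert np.mean(hats) > 0.85


class TestACE:
    def test_two_tip_equal_branches(self):
        tree = read_newick("(A:3,B:3);")
        st = ls.ace_bm(tree, {"A": 4.0, "B": 2.0})
        assert st.estimates[tree.root.id] == pytest.approx(3.0)

    def test_two_tip_weighted_closed_form(self):
        tree = read_newick("(A:2,B:1);")
        st = ls.ace_bm(tree, {"A": 3.0, "B": 0.0})
        expect = (3.0 / 2 + 0.0 / 1) / (1 / 2 + 1 / 1)
        assert st.estimates[tree.root.id] == pytest.approx(expect)

    def test_tips_carry_observations(self):
        tree = _random_calibrated_tree(4)
        vals = {t.label: float(i) for i, t in enumerate(tree.tips)}
        st = ls.ace_bm(tree, vals)
        for t in tree.tips:
            assert st.estimates[t.id] == vals[t.label]
            assert st.variances[t.id] == 0.0

    def test_matches_rerooting_gls_oracle(self):
        # every internal node equals the GLS root estimate of the rerooted
        # tree, built independently from pairwise path distances
        for seed in range(10):
            tree = _random_calibrated_tree(seed, n=8)
            vals = ls.simulate_traits(tree, 0.3, seed=50 + seed)
            x = {t.label: vals[t.id] for t in tree.tips}
            st = ls.ace_bm(tree, x)
            depths = tree.depths()
            anc = {}
            for node in tree.preorder():
                anc[node.id] = (anc[node.parent.id] | {node.parent.id}) \
                    if node.parent else set()

            def dist(a, b):
                shared = (anc[a] | {a}) & (anc[b] | {b})
                return depths[a] + depths[b] - 2 * max(
                    depths[s] for s in shared)

            tips = tree.tips
            xv = np.array([x[t.label] for t in tips])
            for node in tree.preorder():
                if node.is_leaf:
                    continue
                n = len(tips)
                Cp = np.array([[(dist(node.id, a.id) + dist(node.id, b.id)
                                 - dist(a.id, b.id)) / 2
                                for b in tips] for a in tips])
                Cp += np.eye(n) * 1e-12
                w = np.linalg.solve(Cp, np.ones(n))
                expect = float(xv @ w / w.sum())
                assert st.estimates[node.id] == pytest.approx(expect,
                                                              abs=1e-9)

    def test_linear_in_trait(self):
        tree = _random_calibrated_tree(6)
        vals = ls.simulate_traits(tree, 0.2, seed=9)
        x = {t.label: vals[t.id] for t in tree.tips}
        st1 = ls.ace_bm(tree, x)
        st2 = ls.ace_bm(tree, {k: 3.0 * v - 2.0 for k, v in x.items()})
        for nid, e in st1.estimates.items():
            assert st2.estimates[nid] == pytest.approx(3.0 * e - 2.0,
                                                       abs=1e-9)


class TestPhylomorphospace:
    def test_two_tip_midpoint_and_tip_identity(self):
        tree = read_newick("(A:2,B:2);")
        scores = {"A": (1.0, 0.0), "B": (0.0, 1.0)}
        pms = ls.phylomorphospace(tree, scores)
        root = pms["coordinates"][tree.root.id]
        np.testing.assert_allclose(root, [0.5, 0.5])
        for t in tree.tips:
            np.testing.assert_allclose(pms["coordinates"][t.id],
                                       scores[t.label])

    def test_segment_count(self):
        tree = _random_calibrated_tree(8, n=9)
        rng = np.random.default_rng(0)
        scores = {t.label: rng.standard_normal(2) for t in tree.tips}
        pms = ls.phylomorphospace(tree, scores)
        assert len(pms["segments"]) == tree.n_nodes - 1

    def test_missing_tip_rejected(self):
        tree = read_newick("(A:1,(B:1,C:1):1);")
        with pytest.raises(ComparativeError):
            ls.phylomorphospace(tree, {"A": (0, 0), "B": (1, 1)})


class TestPhyloANOVA:
    def test_constant_response(self):
        tree = _random_calibrated_tree(3, n=6)
        groups = dict(zip(tree.tip_labels, ["a", "a", "b", "b", "a", "b"]))
        res = ls.phylo_anova(tree, dict.fromkeys(tree.tip_labels, 2.0),
                             groups, n_sim=100, seed=0)
        assert res.ss_total == 0.0
        assert res.r_squared == 0.0
        assert res.p == 1.0

    def test_f_and_ss_match_textbook_oracle(self):
        # phylogeny shapes only the null distribution; the observed F and
        # SS decomposition are ordinary one-way ANOVA
        tree = read_newick("((A:1,B:1):1,(C:1,(D:1,E:0.5):1):1,F:2);")
        x = {"A": 1.0, "B": 2.0, "C": 5.0, "D": 6.0, "E": 4.0, "F": 2.5}
        groups = {"A": "g1", "B": "g1", "C": "g2", "D": "g2",
                  "E": "g2", "F": "g1"}
        res = ls.phylo_anova(tree, x, groups, n_sim=100, seed=1)
        g1 = [1.0, 2.0, 2.5]
        g2 = [5.0, 6.0, 4.0]
        grand = np.mean(g1 + g2)
        ssf = 3 * (np.mean(g1) - grand) ** 2 + 3 * (np.mean(g2) - grand) ** 2
        sst = sum((v - grand) ** 2 for v in g1 + g2)
        ssr = sst - ssf
        f = (ssf / 1) / (ssr / 4)
        assert res.ss_factor == pytest.approx(ssf, abs=1e-9)
        assert res.ss_residual == pytest.approx(ssr, abs=1e-9)
        assert res.F == pytest.approx(f, abs=1e-9)
        assert res.ss_factor + res.ss_residual == pytest.approx(
            res.ss_total, abs=1e-9)

    def test_single_group_rejected(self):
        tree = _random_calibrated_tree(5, n=4)
        with pytest.raises(ComparativeError):
            ls.phylo_anova(tree, dict(zip(tree.tip_labels, [1, 2, 3, 4])),
                           dict.fromkeys(tree.tip_labels, "g"), n_sim=100)


class TestSimulateTraits:
    def test_zero_rate_constant(self):
        tree = _random_calibrated_tree(7)
        vals = ls.simulate_traits(tree, 0.0, mu=0.0, seed=1, root_state=5.0)
        assert all(v == pytest.approx(5.0) for v in vals.values())

    def test_tip_variance_closed_form(self):
        tree = read_newick("(A:12,B:12);")
        rng = np.random.default_rng(0)
        tipvals = []
        for _ in range(2000):
            vals = ls.simulate_traits(tree, 0.5, rng=rng)
            tipvals.append(vals[tree.tips[0].id])
        assert np.var(tipvals) == pytest.approx(0.5 * 12, rel=0.1)

    def test_negative_drift_direction(self):
        from scipy import stats as sps
        tree = _random_calibrated_tree(12, n=16)
        below = 0
        for seed in range(200):
            vals = ls.simulate_traits(tree, 0.01, mu=-0.05, seed=seed,
                                      root_state=1.0)
            tips = [vals[t.id] for t in tree.tips]
            below += np.mean(tips) < 1.0
        # sign test: drift must pull tip means below the root state
        p = sps.binomtest(below, 200, 0.5, alternative="greater").pvalue
        assert p < 0.01
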