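"""Hierarchical priors, root posteriors, stochastic maps, association."""

import numpy as np
import pytest
from scipy import stats

import phylocoev as pc
from phylocoev.likelihood import log_likelihood
from phylocoev.ratemodels import RootPolicy
from phylocoev.simmap import (PriorConfig, _uniformization_branch,
                              binary_generator, joint_dwell_fractions,
                              sample_change_count_uniformization)

from conftest import random_tree


def small_sample(seed=0, n_taxa=8, n_trees=3):
    return pc.simulate_tree_sample(pc.ScenarioConfig(
        n_taxa=n_taxa, n_outgroup=2, n_trees=n_trees, seed=seed))


def binary_data(trees, labels):
    taxa = sorted(trees.taxa)
    return pc.CharacterData.from_labels(
        ("0", "1"), {t: labels[i % len(labels)] for i, t in enumerate(taxa)})


class TestPriorConfig:
    def test_grids_are_quantile_midpoints(self):
        pc_ = PriorConfig(2.0, 3.0, 1.5, n_grid=5)
        g, w = pc_.rate_grid()
        qs = (np.arange(5) + 0.5) / 5
        assert np.allclose(g, stats.gamma.ppf(qs, 3.0, scale=1 / 1.5))
        assert np.allclose(w, 0.2)

    def test_empirical_bias_is_point_mass(self):
        trees = small_sample()
        data = binary_data(trees, ["0", "0", "1"])
        g, w = PriorConfig(None, 1.0, 1.0).bias_grid(data)
        assert len(g) == 1 and w[0] == 1.0
        assert g[0] == pytest.approx(data.frequencies()[1])

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            PriorConfig(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            PriorConfig(1.0, 0.0, 1.0)


class TestBiasPriorFit:
    def test_balanced_data_prefers_large_alpha(self):
        trees = small_sample(seed=1)
        data = binary_data(trees, ["0", "1"])  # alternating, 50/50
        fit = pc.fit_bias_prior(data, trees, n_grid=9)
        assert float(fit) > 2.0

    def test_biased_data_fits_smaller_alpha_than_balanced(self):
        rng = np.random.default_rng(0)
        lower = 0
        reps = 12
        for i in range(reps):
            trees = small_sample(seed=100 + i, n_trees=2)
            Q_biased = binary_generator(0.9, 2.0)
            d_biased, _ = pc.simulate_character(
                trees[0], Q_biased, RootPolicy.fixed(1), rng,
                state_space=["0", "1"])
            balanced = binary_data(trees, ["0", "1"])
            a_bias = float(pc.fit_bias_prior(d_biased, trees, n_grid=7))
            a_bal = float(pc.fit_bias_prior(balanced, trees, n_grid=7))
            lower += a_bias < a_bal
        assert lower > reps / 2

    def test_boundary_flagged(self):
        trees = small_sample(seed=2)
        data = binary_data(trees, ["0", "1"])
        with pytest.warns(UserWarning, match="boundary"):
            fit = pc.fit_bias_prior(data, trees, n_grid=7)
        assert fit.boundary

    def test_nonbinary_and_degenerate_rejected(self):
        trees = small_sample()
        male = pc.CharacterData.from_labels(
            ("S+P-", "S-P-", "S-P+"),
            {t: "S+P-" for t in trees.taxa})
        with pytest.raises(ValueError):
            pc.fit_bias_prior(male, trees)
        lone = pc.CharacterData(["0", "1"],
                                {t: (-1 if i else 0)
                                 for i, t in enumerate(sorted(trees.taxa))})
        with pytest.raises(ValueError):
            pc.fit_bias_prior(lone, trees)


class TestRatePriorFit:
    def test_recovers_rate_scale(self):
        # slow-rate data on the generating tree: fitted Gamma mean lands
        # within a factor of 3 of the truth in most replicates, and
        # fast-rate data always fits a higher mean than slow-rate data
        rng = np.random.default_rng(1)
        ok = wins = 0
        reps = 12
        for i in range(reps):
            trees = small_sample(seed=200 + i, n_taxa=29, n_trees=1)
            slow, _ = pc.simulate_character(
                trees[0], binary_generator(0.5, 0.3),
                RootPolicy.uniform(), rng, state_space=["0", "1"])
            fast, _ = pc.simulate_character(
                trees[0], binary_generator(0.5, 5.0),
                RootPolicy.uniform(), rng, state_space=["0", "1"])
            fs = pc.fit_rate_prior(slow, trees, n_grid=9)
            ff = pc.fit_rate_prior(fast, trees, n_grid=9)
            ms = fs.value[0] / fs.value[1]
            mf = ff.value[0] / ff.value[1]
            ok += 0.1 <= ms <= 0.9
            wins += mf > ms
        assert ok >= 7
        assert wins >= 8

    def test_constant_character_fits_lower_rate_than_variable(self):
        trees = small_sample(seed=3)
        const = binary_data(trees, ["0"])
        varied = binary_data(trees, ["0", "1"])
        f_const = pc.fit_rate_prior(const, trees, n_grid=9)
        f_var = pc.fit_rate_prior(varied, trees, n_grid=9)
        assert (f_const.value[0] / f_const.value[1]
                < f_var.value[0] / f_var.value[1])

    def test_deterministic(self):
        trees = small_sample(seed=4)
        data = binary_data(trees, ["0", "1", "1"])
        assert pc.fit_rate_prior(data, trees).value == \
            pc.fit_rate_prior(data, trees).value


class TestRootPosterior:
    def test_constant_character_point_mass(self):
        trees = small_sample(seed=5)
        data = binary_data(trees, ["1"])
        priors = PriorConfig(2.0, 2.0, 4.0)  # rate prior mean 0.5 per unit height
        post = pc.root_marginal_posterior(trees, data, priors)
        assert post.sum() == pytest.approx(1.0)
        assert post[1] >= 0.99

    def test_symmetric_arrangement_is_half_half(self):
        tree = pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        trees = pc.TreeSample([tree])
        data = pc.CharacterData(["0", "1"], {"A": 0, "B": 1, "C": 1, "D": 0})
        post = pc.root_marginal_posterior(trees, data,
                                          PriorConfig(3.0, 2.0, 2.0))
        assert post[0] == pytest.approx(0.5, abs=1e-9)

    def test_three_taxon_matches_direct_sum(self):
        tree = pc.read_newick("((A:0.5,B:0.5):0.5,C:1);")
        trees = pc.TreeSample([tree])
        data = pc.CharacterData(["0", "1"], {"A": 0, "B": 0, "C": 1})
        priors = PriorConfig(None, 3.0, 3.0, n_grid=7)
        post = pc.root_marginal_posterior(trees, data, priors)
        # direct computation: same grid, likelihood by enumeration
        p1 = data.frequencies()[1]
        r_grid, rw = priors.rate_grid()
        num = np.zeros(2)
        for r, w in zip(r_grid, rw):
            Q = binary_generator(p1, r)
            from scipy.linalg import expm
            P05 = expm(Q * 0.5)
            P1 = expm(Q * 1.0)
            pi = np.array([1 - p1, p1])
            for root in (0, 1):
                lik = 0.0
                for mid in (0, 1):
                    lik += P05[root, mid] * P05[mid, 0] * P05[mid, 0]
                lik *= P1[root, 1]
                num[root] += w * pi[root] * lik
        assert post == pytest.approx(num / num.sum(), abs=1e-10)


class TestStochasticMap:
    def test_near_zero_rate_constant_history(self):
        tree = pc.read_newick("((A:1,B:1):1,C:2);")
        data = pc.CharacterData(["0", "1"], {"A": 0, "B": 0, "C": 0})
        Q = binary_generator(0.5, 1e-8)
        h = pc.stochastic_map(tree, data, Q, seed=0)
        h.validate()
        assert h.n_changes() == 0

    def test_every_draw_satisfies_invariants_and_tips(self):
        rng = np.random.default_rng(3)
        tree = random_tree(rng, n=6)
        taxa = sorted(tree.taxa)
        data = pc.CharacterData(["0", "1"],
                                {t: i % 2 for i, t in enumerate(taxa)})
        Q = binary_generator(0.4, 1.5)
        for seed in range(40):
            h = pc.stochastic_map(tree, data, Q, seed=seed)
            h.validate()
            for v in tree.leaves():
                assert h.node_states[v] == data.assignments[tree.labels[v]]

    def test_free_endpoint_changes_match_poisson_mean(self):
        # symmetric chain, unconditioned: E[#changes] = rate * t
        tree = pc.read_newick("(A:2,B:0.0001);")
        data = pc.CharacterData(["0", "1"], {"A": -1, "B": -1})
        a = 1.2
        Q = np.array([[-a, a], [a, -a]])
        rng = np.random.default_rng(7)
        counts = []
        for _ in range(4000):
            h = pc.stochastic_map(tree, data, Q, seed=rng)
            counts.append(len(h.segments[[v for v in tree.leaves()
                                          if tree.labels[v] == "A"][0]]) - 1)
        mean = np.mean(counts)
        expect = a * 2
        assert abs(mean - expect) < 4 * np.sqrt(expect / len(counts))

    def test_node_marginals_match_pruning(self):
        tree = pc.read_newick("((A:0.7,B:0.7):0.5,(C:0.4,D:0.8):0.4);")
        data = pc.CharacterData(["0", "1"], {"A": 0, "B": 1, "C": 1, "D": 1})
        Q = binary_generator(0.6, 1.0)
        from phylocoev.likelihood import node_marginals
        M = node_marginals(tree, data, Q)
        rng = np.random.default_rng(11)
        n = 8000
        counts = np.zeros((tree.n_nodes, 2))
        for _ in range(n):
            h = pc.stochastic_map(tree, data, Q, seed=rng)
            for v in range(tree.n_nodes):
                counts[v, h.node_states[v]] += 1
        emp = counts / n
        tv = 0.5 * np.abs(emp - M).sum(axis=1).max()
        assert tv < 0.02

    @staticmethod
    def _exact_change_distribution(Q, a, b, t, max_jumps=30):
        """Endpoint-conditioned distribution of *real* change counts from
        the uniformization series (independent closed-form oracle)."""
        k = Q.shape[0]
        mu = float(np.max(-np.diag(Q)))
        R = np.eye(k) + Q / mu
        # W[n][s, c]: prob of being in state s with c real changes after
        # n uniformized jumps, starting from a
        W = np.zeros((k, max_jumps + 1))
        W[a, 0] = 1.0
        out = np.zeros(max_jumps + 1)
        out += stats.poisson.pmf(0, mu * t) * W[b]
        for n in range(1, max_jumps + 1):
            W2 = np.zeros_like(W)
            for s in range(k):
                for s2 in range(k):
                    if s == s2:
                        W2[s2] += R[s, s2] * W[s]
                    else:
                        W2[s2, 1:] += R[s, s2] * W[s, :-1]
            W = W2
            out += stats.poisson.pmf(n, mu * t) * W[b]
        return out / out.sum()

    @pytest.mark.parametrize("sampler", ["rejection", "uniformization"])
    def test_change_counts_match_exact_distribution(self, sampler):
        """Endpoint-conditioned change counts from both path samplers match
        the closed-form uniformization series (chi-square GOF)."""
        Q = binary_generator(0.4, 1.0)
        t, a, b = 1.5, 0, 1
        exact = self._exact_change_distribution(Q, a, b, t)
        rng = np.random.default_rng(5 if sampler == "rejection" else 6)
        n = 6000
        if sampler == "rejection":
            from phylocoev.likelihood import _simulate_branch
            draws = []
            while len(draws) < n:
                end, segs = _simulate_branch(rng, Q, a, t)
                if end == b:
                    draws.append(len(segs) - 1)
        else:
            draws = [sample_change_count_uniformization(rng, Q, a, b, t)
                     for _ in range(n)]
        cats = [1, 3]
        obs = np.array([sum(1 for x in draws if x == c) for c in cats]
                       + [sum(1 for x in draws if x > 3)])
        probs = np.array([exact[1], exact[3], exact[5:].sum()])
        chi2, p = stats.chisquare(obs, probs * n)
        assert p > 0.01

    def test_uniformization_branch_valid_segments(self):
        Q = binary_generator(0.3, 2.0)
        rng = np.random.default_rng(8)
        for _ in range(200):
            segs = _uniformization_branch(rng, Q, 0, 1, 1.0)
            assert segs[0][0] == 0 and segs[-1][0] == 1
            assert sum(ln for _, ln in segs) == pytest.approx(1.0)
            for (s1, _), (s2, _) in zip(segs, segs[1:]):
                assert s1 != s2


class TestDwellAndAssociation:
    def test_dwell_fractions_hand_built(self):
        tree = pc.read_newick("(A:1,B:1);")
        va = [v for v in tree.leaves() if tree.labels[v] == "A"][0]
        vb = [v for v in tree.leaves() if tree.labels[v] == "B"][0]
        h = pc.CharacterHistory(
            tree, np.array([0, 1, 0]) if va == 1 else np.array([0, 0, 1]),
            {va: [(0, 0.3), (1, 0.7)], vb: [(0, 1.0)]})
        f = pc.dwell_fractions(h, 2)
        assert f == pytest.approx([0.65, 0.35])
        assert f.sum() == pytest.approx(1.0)

    def test_dwell_invariant_to_length_rescaling(self):
        rng = np.random.default_rng(4)
        tree = random_tree(rng, n=5)
        Q = binary_generator(0.5, 1.5)
        _, h = pc.simulate_character(tree, Q, seed=3, state_space=["0", "1"])
        f1 = pc.dwell_fractions(h, 2)
        scaled = tree.copy()
        scaled.lengths = scaled.lengths * 3.7
        h2 = pc.CharacterHistory(
            scaled, h.node_states,
            {v: [(s, ln * 3.7) for s, ln in segs]
             for v, segs in h.segments.items()})
        assert pc.dwell_fractions(h2, 2) == pytest.approx(f1)

    def test_identical_histories_association_algebra(self):
        # maps2 = maps1: m_00 = p0(1-p0), m_01 = -p0 p1
        rng = np.random.default_rng(9)
        tree = random_tree(rng, n=6)
        Q = binary_generator(0.5, 1.0)
        _, h = pc.simulate_character(tree, Q, seed=5, state_space=["0", "1"])
        st = pc.association_stats([h], [h])
        p0, p1 = pc.dwell_fractions(h, 2)
        assert st.m[0, 0] == pytest.approx(p0 * (1 - p0), abs=1e-12)
        assert st.m[0, 1] == pytest.approx(-p0 * p1, abs=1e-12)
        assert st.m.sum() == pytest.approx(0.0, abs=1e-12)

    def test_joint_dwell_sums_to_one_and_marginals_cancel(self):
        rng = np.random.default_rng(10)
        tree = random_tree(rng, n=7)
        Q = binary_generator(0.4, 2.0)
        _, h1 = pc.simulate_character(tree, Q, seed=1, state_space=["0", "1"])
        _, h2 = pc.simulate_character(tree, Q, seed=2, state_space=["0", "1"])
        J = joint_dwell_fractions(h1, h2)
        assert J.sum() == pytest.approx(1.0, abs=1e-9)
        st = pc.association_stats([h1], [h2])
        assert st.m.sum() == pytest.approx(0.0, abs=1e-12)

    def test_unpaired_lists_rejected(self):
        rng = np.random.default_rng(11)
        tree = random_tree(rng, n=5)
        Q = binary_generator(0.5, 1.0)
        _, h = pc.simulate_character(tree, Q, seed=1, state_space=["0", "1"])
        with pytest.raises(ValueError):
            pc.association_stats([h, h], [h])


def test_predictive_sample_count():
    assert pc.predictive_sample_count(431, 10, 10) == 43_100
    with pytest.raises(ValueError):
        pc.predictive_sample_count(0, 10, 10)
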