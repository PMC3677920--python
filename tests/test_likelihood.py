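"""Pruning likelihood against closed forms and enumeration; CTMC simulation."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import phylocoev as pc
from phylocoev.likelihood import log_likelihood, node_marginals, transition_matrices
from phylocoev.ratemodels import RootPolicy

from conftest import random_character, random_generator_matrix, random_tree


def brute_force_loglik(tree, data, Q, pi):
    """Sum over all internal-node state assignments (enumeration oracle)."""
    k = Q.shape[0]
    P = {v: expm(Q * tree.lengths[v]) for v in range(tree.n_nodes)}
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    tot = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        for v in tree.leaves():
            st[v] = data.assignments[tree.labels[v]]
        p = pi[st[tree.root]]
        for v in range(tree.n_nodes):
            if tree.parent[v] >= 0:
                p *= P[v][st[tree.parent[v]], st[v]]
        tot += p
    return np.log(tot) if tot > 0 else -np.inf


class TestPruning:
    def test_zero_length_star_probability_one(self):
        t = pc.read_newick("(A:0,B:0,C:0);")
        data = pc.CharacterData(["0", "1"], {"A": 0, "B": 0, "C": 0})
        Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        assert log_likelihood(t, data, Q, RootPolicy.fixed(0)) == pytest.approx(0.0)

    def test_single_branch_closed_form(self):
        # P00(t) = 1/2 (1 + e^{-2 a t}) for the symmetric 2-state chain
        t = pc.read_newick("(A:1,B:1);")
        a = 0.5
        Q = np.array([[-a, a], [a, -a]])
        data = pc.CharacterData(["0", "1"], {"A": 0, "B": -1})
        ll = log_likelihood(t, data, Q, RootPolicy.fixed(0))
        assert ll == pytest.approx(np.log(0.5 * (1 + np.exp(-1.0))), abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(15):
            k = int(rng.integers(2, 5))
            t = random_tree(rng, n=int(rng.integers(2, 7)))
            Q = random_generator_matrix(rng, k)
            data = random_character(rng, t, k)
            a = log_likelihood(t, data, Q, RootPolicy.uniform())
            b = brute_force_loglik(t, data, Q, np.full(k, 1 / k))
            assert a == pytest.approx(b, abs=1e-8)

    def test_missing_tip_contributes_ones(self):
        rng = np.random.default_rng(2)
        t = random_tree(rng, n=4)
        Q = random_generator_matrix(rng, 2)
        taxa = sorted(t.taxa)
        # marginalizing one tip by hand = missing-coded likelihood
        miss = pc.CharacterData(["0", "1"], {taxa[0]: -1, taxa[1]: 0,
                                             taxa[2]: 1, taxa[3]: 0})
        total = None
        for s in (0, 1):
            d = pc.CharacterData(["0", "1"], {**miss.assignments, taxa[0]: s})
            ll = log_likelihood(t, d, Q)
            total = ll if total is None else np.logaddexp(total, ll)
        assert log_likelihood(t, miss, Q) == pytest.approx(total, abs=1e-10)

    def test_taxon_absent_from_data_raises(self, three_taxon_tree):
        data = pc.CharacterData(["0", "1"], {"A": 0, "B": 1})
        Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        with pytest.raises(ValueError, match="C"):
            log_likelihood(three_taxon_tree, data, Q)

    def test_leaf_order_invariance(self):
        rng = np.random.default_rng(8)
        t = random_tree(rng, n=6)
        Q = random_generator_matrix(rng, 3)
        data = random_character(rng, t, 3)
        mirrored = t.copy()
        mirrored.children = [list(reversed(c)) for c in mirrored.children]
        assert log_likelihood(t, data, Q) == pytest.approx(
            log_likelihood(mirrored, data, Q), abs=1e-12)

    def test_impossible_data_minus_inf(self):
        t = pc.read_newick("(A:1,B:1);")
        spec = pc.MALE_2RATE
        Q = pc.build_generator(spec, [1.0, 1.3])
        # state 0 is never re-entered, so a tip in state 0 under a
        # root fixed at state 2 is impossible
        data = pc.CharacterData(list(spec.state_space), {"A": 0, "B": 2})
        assert log_likelihood(t, data, Q, RootPolicy.fixed(2)) == -np.inf


class TestTransitionMatrices:
    def test_rows_stochastic_and_match_expm(self):
        rng = np.random.default_rng(3)
        Q = random_generator_matrix(rng, 4)
        ts = np.array([0.0, 0.1, 1.0, 10.0])
        P = transition_matrices(Q, ts)
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-10)
        for i, t in enumerate(ts):
            assert np.allclose(P[i], expm(Q * t), atol=1e-9)

    def test_defective_generator_falls_back(self):
        # equal-rate 3-state chain template is non-diagonalizable
        Q = pc.build_generator(pc.MALE_2RATE, [1.0, 1.0])
        P = transition_matrices(Q, np.array([0.7]))
        assert np.allclose(P[0], expm(Q * 0.7), atol=1e-9)


class TestJointEmbeddingFactorization:
    def test_joint_likelihood_factorizes(self):
        from phylocoev.ratemodels import ZERO, RateModelSpec
        rng = np.random.default_rng(17)
        a = RateModelSpec("a", ("S+", "S-"), ((ZERO, 0), (1, ZERO)))
        b = RateModelSpec("b", ("B-", "B+"), ((ZERO, 0), (1, ZERO)))
        joint_spec = pc.joint_embedding(a, b)
        for _ in range(6):
            t = random_tree(rng, n=6)
            ra = rng.uniform(0.2, 2.0, 2)
            rb = rng.uniform(0.2, 2.0, 2)
            da = random_character(rng, t, 2, labels=("S+", "S-"))
            db = random_character(rng, t, 2, labels=("B-", "B+"))
            dj = pc.combine_binary(da, db)
            lj = log_likelihood(t, dj, pc.build_generator(
                joint_spec, np.concatenate([ra, rb])))
            la = log_likelihood(t, da, pc.build_generator(a, ra))
            lb = log_likelihood(t, db, pc.build_generator(b, rb))
            assert lj == pytest.approx(la + lb, abs=1e-10)


class TestSimulation:
    def test_zero_generator_constant(self, three_taxon_tree):
        Q = np.zeros((2, 2))
        data, hist = pc.simulate_character(three_taxon_tree, Q,
                                           RootPolicy.fixed(1), seed=1)
        assert set(data.assignments.values()) == {1}
        assert hist.n_changes() == 0
        hist.validate()

    def test_long_branch_stationary_frequencies(self):
        t = pc.read_newick("(A:50,B:50);")
        Q = np.array([[-1.0, 1.0], [1.0, -1.0]])
        rng = np.random.default_rng(4)
        hits = 0
        n = 4000
        for _ in range(n):
            data, _ = pc.simulate_character(t, Q, RootPolicy.fixed(0), rng)
            hits += data.assignments["A"]
        freq = hits / n
        assert abs(freq - 0.5) < 3 * 0.5 / np.sqrt(n)

    def test_male_chain_never_regains_sacs(self):
        Q = pc.build_generator(pc.MALE_2RATE, [2.0, 2.0])
        rng = np.random.default_rng(6)
        for _ in range(50):
            t = random_tree(rng, n=8)
            _, hist = pc.simulate_character(t, Q, RootPolicy.fixed(0), rng)
            for segs in hist.segments.values():
                states = [s for s, _ in segs]
                for x, y in zip(states, states[1:]):
                    assert y > x  # strictly down the chain
            hist.validate()

    def test_history_invariants_random(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            t = random_tree(rng)
            Q = random_generator_matrix(rng, 3)
            _, hist = pc.simulate_character(t, Q, RootPolicy.uniform(), rng)
            hist.validate()


class TestNodeMarginals:
    def test_rows_normalized_and_match_enumeration(self):
        rng = np.random.default_rng(23)
        t = random_tree(rng, n=4)
        Q = random_generator_matrix(rng, 2)
        data = random_character(rng, t, 2)
        M = node_marginals(t, data, Q)
        assert np.allclose(M.sum(axis=1), 1.0)
        # root marginal by direct conditioning
        lls = []
        for s in (0, 1):
            lls.append(brute_force_loglik(t, data, Q, np.array(
                [0.5 if i == s else 0.0 for i in range(2)])))
        w = np.exp(np.array(lls))
        assert M[t.root] == pytest.approx(w / w.sum(), abs=1e-9)
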