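"""Felsenstein pruning likelihood, CTMC simulation and character histories.

The likelihood of a categorical character on a rooted tree under a
generator matrix Q is

    L = sum_s pi(s) * F_root(s)

where the conditional (partial) likelihoods F are accumulated tipward
-> rootward with per-branch transition probabilities P(t) = expm(Q t).
Transition matrices are computed by eigendecomposition vectorized over
branches, with a scipy ``expm`` fallback when Q is ill-conditioned.
Missing tip states contribute an all-ones partial likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .characters import MISSING, CharacterData
from .ratemodels import RootPolicy
from .trees import RootedTree

__all__ = [
    "log_likelihood", "transition_matrices", "simulate_character",
    "CharacterHistory", "TreeIndex", "node_marginals",
]

_EXPM_COND_MAX = 1e8


def transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = expm(Q t) for every t in ``lengths`` (shape (B, k, k)).

    Uses one eigendecomposition of Q when it is well-conditioned,
    otherwise falls back to scipy's scaling-and-squaring per branch.
    Small negative round-off entries are clipped to zero.
    """
    lengths = np.asarray(lengths, dtype=float)
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        cond = np.linalg.cond(V)
        if not np.isfinite(cond) or cond > _EXPM_COND_MAX:
            raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        E = np.exp(np.multiply.outer(lengths, w))  # (B, k)
        P = np.einsum("ij,bj,jk->bik", V, E, Vinv)
        P = np.real_if_close(P, tol=1e6)
        P = np.real(P)
    except np.linalg.LinAlgError:
        P = np.stack([expm(Q * t) for t in lengths])
    np.clip(P, 0.0, None, out=P)
    # kill eigendecomposition residue in structurally-zero entries so that
    # impossible data keep zero likelihood (threshold far below any
    # probability the models can distinguish)
    P[P < 1e-14] = 0.0
    P[lengths == 0.0] = np.eye(k)
    # renormalize rows against round-off
    P /= P.sum(axis=2, keepdims=True)
    return P


@dataclass
class TreeIndex:
    """Flat traversal arrays for one tree, reused across likelihood calls."""

    tree: RootedTree
    postorder: list[int] = field(init=False)
    lengths: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.postorder = self.tree.postorder()
        self.lengths = self.tree.lengths


def _tip_partials(tree: RootedTree, data: CharacterData, k: int) -> np.ndarray:
    F = np.ones((tree.n_nodes, k))
    for v in tree.leaves():
        taxon = tree.labels[v]
        if taxon not in data.assignments:
            raise ValueError(f"taxon {taxon!r} in tree but not in character data")
        s = data.assignments[taxon]
        if s != MISSING:
            F[v] = 0.0
            F[v, s] = 1.0
    return F


def _root_pi(Q_k: int, root_policy: RootPolicy, data: CharacterData) -> np.ndarray:
    return root_policy.pi(Q_k, data.frequencies())


def _pruning(tree: RootedTree, data: CharacterData, Q: np.ndarray,
             index: TreeIndex | None = None) -> tuple[np.ndarray, float, np.ndarray]:
    """Partial likelihoods at every node (scaled), the summed log scaler
    at the root, and the per-branch transition matrices."""
    k = Q.shape[0]
    idx = index or TreeIndex(tree)
    P = transition_matrices(Q, idx.lengths)
    F = _tip_partials(tree, data, k)
    logscale = np.zeros(tree.n_nodes)
    for v in idx.postorder:
        kids = tree.children[v]
        if not kids:
            continue
        part = np.ones(k)
        ls = 0.0
        for c in kids:
            part = part * (P[c] @ F[c])
            ls += logscale[c]
        m = part.max()
        if m <= 0:
            # impossible data under Q; signal via -inf scaling
            logscale[v] = -np.inf
            F[v] = np.full(k, 1.0 / k)
            continue
        F[v] = part / m
        logscale[v] = ls + np.log(m)
    return F, float(logscale[tree.root]), P


def log_likelihood(tree: RootedTree, data: CharacterData, Q: np.ndarray,
                   root_policy: RootPolicy | None = None,
                   index: TreeIndex | None = None) -> float:
    """Log likelihood of the tip data under Q by Felsenstein pruning."""
    root_policy = root_policy or RootPolicy.uniform()
    F, logscale, _ = _pruning(tree, data, Q, index)
    pi = _root_pi(Q.shape[0], root_policy, data)
    lik = float(pi @ F[tree.root])
    if lik <= 0 or not np.isfinite(logscale):
        return -np.inf
    return np.log(lik) + logscale


def node_marginals(tree: RootedTree, data: CharacterData, Q: np.ndarray,
                   root_policy: RootPolicy | None = None) -> np.ndarray:
    """Marginal posterior state probabilities at every node.

    Computed by an outside pass on top of the pruning partials.
    """
    root_policy = root_policy or RootPolicy.uniform()
    k = Q.shape[0]
    F, logscale, P = _pruning(tree, data, Q)
    if not np.isfinite(logscale):
        raise ValueError("data have zero likelihood under Q")
    pi = _root_pi(k, root_policy, data)
    G = np.zeros_like(F)  # outside (above-node) partials, unnormalized
    order = list(reversed(tree.postorder()))
    G[tree.root] = pi
    for v in order:
        for c in tree.children[v]:
            # sibling contribution at v
            sib = np.ones(k)
            for c2 in tree.children[v]:
                if c2 != c:
                    sib = sib * (P[c2] @ F[c2])
            above = G[v] * sib
            G[c] = above @ P[c]
            m = G[c].max()
            if m > 0:
                G[c] = G[c] / m
    M = F * G
    M /= M.sum(axis=1, keepdims=True)
    return M


@dataclass
class CharacterHistory:
    """Piecewise-constant state assignment along every branch.

    ``segments[v]`` lists (state, length) pairs on the branch above node
    v, ordered rootward -> tipward; ``node_states[v]`` is the state at
    node v.  Segment lengths on a branch sum to the branch length and
    adjacent segments differ in state.
    """

    tree: RootedTree
    node_states: np.ndarray
    segments: dict[int, list[tuple[int, float]]]

    def validate(self, atol: float = 1e-9) -> None:
        for v, segs in self.segments.items():
            total = sum(s for _, s in segs)
            if abs(total - self.tree.lengths[v]) > atol * max(1.0, self.tree.lengths[v]):
                raise ValueError(f"segments on branch {v} do not sum to its length")
            for (a, _), (b, _) in zip(segs, segs[1:]):
                if a == b:
                    raise ValueError("adjacent segments share a state")
            if segs and segs[-1][0] != self.node_states[v]:
                raise ValueError("last segment state differs from node state")
            p = self.tree.parent[v]
            if segs and p >= 0 and segs[0][0] != self.node_states[p]:
                raise ValueError("first segment state differs from parent state")

    def n_changes(self) -> int:
        return sum(max(0, len(s) - 1) for s in self.segments.values())

    def dwell_times(self, k: int) -> np.ndarray:
        t = np.zeros(k)
        for segs in self.segments.values():
            for s, ln in segs:
                t[s] += ln
        return t

    def tip_data(self, state_space: list[str]) -> CharacterData:
        return CharacterData(
            list(state_space),
            {self.tree.labels[v]: int(self.node_states[v])
             for v in self.tree.leaves()})


def _simulate_branch(rng: np.random.Generator, Q: np.ndarray, start: int,
                     t: float) -> tuple[int, list[tuple[int, float]]]:
    """Forward CTMC path of duration t from ``start``; returns the end
    state and the segment list."""
    segs: list[tuple[int, float]] = []
    s = start
    remaining = t
    while True:
        rate = -Q[s, s]
        if rate <= 0:
            segs.append((s, remaining))
            return s, segs
        wait = rng.exponential(1.0 / rate)
        if wait >= remaining:
            segs.append((s, remaining))
            return s, segs
        segs.append((s, wait))
        remaining -= wait
        probs = Q[s].copy()
        probs[s] = 0.0
        probs = probs / probs.sum()
        s = int(rng.choice(len(probs), p=probs))


def _merge_zero_segments(segs: list[tuple[int, float]]) -> list[tuple[int, float]]:
    out: list[tuple[int, float]] = []
    for s, ln in segs:
        if out and out[-1][0] == s:
            out[-1] = (s, out[-1][1] + ln)
        else:
            out.append((s, ln))
    return out


def simulate_character(tree: RootedTree, Q: np.ndarray,
                       root_policy: RootPolicy | None = None,
                       seed: int | np.random.Generator = 0,
                       tip_frequencies=None,
                       state_space: list[str] | None = None,
                       ) -> tuple[CharacterData, CharacterHistory]:
    """Simulate a character down the tree under the CTMC Q.

    The root state is drawn from the root policy; each branch evolves by
    exponential waiting times.  Returns the tip data and the full
    piecewise-constant history.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root_policy = root_policy or RootPolicy.uniform()
    k = Q.shape[0]
    pi = root_policy.pi(k, tip_frequencies)
    states = np.zeros(tree.n_nodes, dtype=int)
    segments: dict[int, list[tuple[int, float]]] = {}
    states[tree.root] = int(rng.choice(k, p=pi))
    for v in reversed(tree.postorder()):  # preorder
        if v == tree.root:
            continue
        end, segs = _simulate_branch(rng, Q, states[tree.parent[v]], tree.lengths[v])
        states[v] = end
        segments[v] = _merge_zero_segments(segs)
    space = state_space or [f"s{i}" for i in range(k)]
    hist = CharacterHistory(tree, states, segments)
    return hist.tip_data(space), hist
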