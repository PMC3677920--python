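"""Fitch and Sankoff parsimony with asymmetric (Dollo-style) costs.

The "no parallel gains" assumption for complex structures (here, the
gift-bearing penile sacs) is encoded as a prohibitive but finite regain
cost, which forces reconstructions in which the structure arises once
and is only ever lost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .characters import MISSING, CharacterData
from .trees import RootedTree

__all__ = [
    "CostMatrix", "fitch_count", "sankoff", "count_transitions",
    "dollo_costs", "uniform_costs", "SankoffResult",
]

PROHIBITIVE = 1e6


@dataclass(frozen=True)
class CostMatrix:
    """k x k nonnegative transition costs with a zero diagonal."""

    costs: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        k = len(self.costs)
        for i, row in enumerate(self.costs):
            if len(row) != k:
                raise ValueError("cost matrix must be square")
            if row[i] != 0:
                raise ValueError("diagonal costs must be 0")
            if any(c < 0 for c in row):
                raise ValueError("costs must be nonnegative")

    @property
    def k(self) -> int:
        return len(self.costs)

    def as_array(self) -> np.ndarray:
        return np.array(self.costs, dtype=float)

    def to_tsv(self, state_space: list[str] | None = None) -> str:
        labels = state_space or [str(i) for i in range(self.k)]
        lines = ["\t" + "\t".join(labels)]
        for i, row in enumerate(self.costs):
            lines.append(labels[i] + "\t" + "\t".join(f"{c:g}" for c in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "CostMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        rows = []
        for ln in lines[1:]:
            rows.append(tuple(float(x) for x in ln.split("\t")[1:]))
        return cls(tuple(rows))


def uniform_costs(k: int) -> CostMatrix:
    return CostMatrix(tuple(tuple(0.0 if i == j else 1.0 for j in range(k))
                            for i in range(k)))


def dollo_costs(gain_state: int = 0, k: int = 2,
                prohibitive: float = PROHIBITIVE) -> CostMatrix:
    """Loss of ``gain_state`` costs 1; regaining it is prohibitive.

    For the sac character coded (S+, S-) with gain_state=0 this forbids
    parallel gains of the sacs.
    """
    rows = []
    for i in range(k):
        row = []
        for j in range(k):
            if i == j:
                row.append(0.0)
            elif j == gain_state:
                row.append(prohibitive)
            else:
                row.append(1.0)
        rows.append(tuple(row))
    return CostMatrix(tuple(rows))


def fitch_count(tree: RootedTree, data: CharacterData) -> int:
    """Minimum number of state changes (unordered character, Fitch).

    Missing data are not supported here; use :func:`sankoff`, which
    treats a missing tip as an all-states set.
    """
    sets: dict[int, frozenset[int]] = {}
    changes = 0
    for v in tree.postorder():
        if not tree.children[v]:
            s = data.assignments.get(tree.labels[v])
            if s is None:
                raise ValueError(f"taxon {tree.labels[v]!r} not in character data")
            if s == MISSING:
                raise ValueError("missing data: use sankoff with expanded tip sets")
            sets[v] = frozenset([s])
        else:
            acc: frozenset[int] | None = None
            for c in tree.children[v]:
                if acc is None:
                    acc = sets[c]
                    continue
                inter = acc & sets[c]
                if inter:
                    acc = inter
                else:
                    acc = acc | sets[c]
                    changes += 1
            sets[v] = acc
    return changes


@dataclass
class SankoffResult:
    """Minimum-cost reconstruction under a cost matrix."""

    min_cost: float
    node_state_sets: dict[int, frozenset[int]]  # states in >=1 optimal labeling
    labeling: np.ndarray                        # one optimal labeling (tie-broken)
    infeasible: bool

    def assignment(self) -> dict[int, int]:
        return {v: int(s) for v, s in enumerate(self.labeling)}


def sankoff(tree: RootedTree, data: CharacterData, costs: CostMatrix,
            prohibitive: float = PROHIBITIVE) -> SankoffResult:
    """Dynamic-programming minimum-cost ancestral reconstruction.

    Missing tips get an all-states tip set.  Ties in the reported single
    labeling break to the lower state index after the down-pass; the
    full per-node optimal state sets are also returned so transition
    counts can be reported as ranges.
    """
    k = costs.k
    C = costs.as_array()
    INF = np.inf
    up = np.zeros((tree.n_nodes, k))
    for v in tree.postorder():
        if not tree.children[v]:
            s = data.assignments.get(tree.labels[v])
            if s is None:
                raise ValueError(f"taxon {tree.labels[v]!r} not in character data")
            if s == MISSING:
                up[v] = 0.0
            else:
                up[v] = INF
                up[v, s] = 0.0
        else:
            tot = np.zeros(k)
            for c in tree.children[v]:
                # min over child state of (cost(i->j) + up[c, j])
                tot += np.min(C + up[c][None, :], axis=1)
            up[v] = tot
    min_cost = float(up[tree.root].min())
    infeasible = min_cost >= prohibitive

    # one optimal labeling, top-down, lower index wins ties
    labeling = np.zeros(tree.n_nodes, dtype=int)
    labeling[tree.root] = int(np.argmin(up[tree.root]))
    for v in reversed(tree.postorder()):
        for c in tree.children[v]:
            i = labeling[v]
            labeling[c] = int(np.argmin(C[i] + up[c]))

    # per-node sets of states achieving the optimum in some labeling:
    # state s is optimal at v iff down[v, s] + up[v, s] == min_cost,
    # where down[v, s] is the best cost of everything outside v's subtree.
    down = np.zeros((tree.n_nodes, k))
    for v in reversed(tree.postorder()):
        if v == tree.root:
            down[v] = 0.0
            continue
        p = tree.parent[v]
        sib = np.zeros(k)  # per parent-state cost of the other children
        for c2 in tree.children[p]:
            if c2 != v:
                sib += np.min(C + up[c2][None, :], axis=1)
        # best over parent state i of down[p,i] + sib[i] + cost(i -> s)
        down[v] = np.min((down[p] + sib)[:, None] + C, axis=0)
    tol = 1e-9 * max(1.0, abs(min_cost))
    sets = {v: frozenset(int(s) for s in range(k)
                         if down[v, s] + up[v, s] <= min_cost + tol)
            for v in range(tree.n_nodes)}
    return SankoffResult(min_cost, sets, labeling, infeasible)


def count_transitions(tree: RootedTree, assignment: dict[int, int] | np.ndarray,
                      from_state: int, to_state: int) -> int:
    """Count parent->child edges changing from_state -> to_state under a
    full ancestral assignment."""
    a = assignment
    get = (lambda v: int(a[v]))
    n = 0
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0 and get(p) == from_state and get(v) == to_state:
            n += 1
    return n
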