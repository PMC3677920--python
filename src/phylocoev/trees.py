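"""Rooted trees, tree samples and backbone-constraint filtering.

Trees are stored in a flat array representation (parent pointers,
branch lengths, postorder) that the likelihood and mapping engines
consume directly.  Newick parsing and writing go through dendropy;
clade semantics throughout are *rooted*: a clade is the leaf-label set
under an internal node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "RootedTree",
    "TreeSample",
    "read_newick",
    "read_newick_sample",
    "prune_to_taxa",
    "is_ultrametric",
    "satisfies_backbone",
    "filter_by_backbone",
    "max_clade_credibility",
]


class NewickParseError(ValueError):
    """Malformed newick input (unbalanced parentheses, duplicate labels...)."""


@dataclass
class RootedTree:
    """Rooted tree with branch lengths.

    Attributes
    ----------
    parent : int array, parent id per node; -1 for the root.
    lengths : float array, length of the branch above each node
        (0 for the root).
    children : list of child-id lists.
    labels : dict node id -> taxon label (leaves only).
    root : id of the root node.
    """

    parent: np.ndarray
    lengths: np.ndarray
    children: list[list[int]]
    labels: dict[int, str]
    root: int
    node_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        n = len(self.parent)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1 or roots[0] != self.root:
            raise ValueError("tree must have exactly one root")
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be nonnegative")
        labels = list(self.labels.values())
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for v in self.leaves():
            if v not in self.labels:
                raise ValueError(f"leaf node {v} has no taxon label")

    # -- basic accessors ----------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def leaves(self) -> list[int]:
        return [v for v in range(self.n_nodes) if not self.children[v]]

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.labels.values())

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    def depths(self) -> np.ndarray:
        """Distance from the root to every node, accumulated root-down."""
        d = np.zeros(self.n_nodes)
        for v in reversed(self.postorder()):
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def leaf_depth_map(self) -> dict[str, float]:
        d = self.depths()
        return {lab: float(d[v]) for v, lab in self.labels.items()}

    def distance_matrix(self) -> "dict[tuple[str, str], float]":
        """Pairwise path lengths between leaves (via depths + MRCA)."""
        d = self.depths()
        leafsets = self.clade_leafsets(include_leaves=True)
        leaves = {lab: v for v, lab in self.labels.items()}
        out: dict[tuple[str, str], float] = {}
        labs = sorted(leaves)
        # MRCA by smallest clade containing both
        for i, a in enumerate(labs):
            for b in labs[i + 1:]:
                best = None
                for v, ls in leafsets.items():
                    if a in ls and b in ls:
                        if best is None or len(ls) < len(leafsets[best]):
                            best = v
                dist = d[leaves[a]] + d[leaves[b]] - 2 * d[best]
                out[(a, b)] = out[(b, a)] = float(dist)
        return out

    def clade_leafsets(self, include_leaves: bool = False) -> dict[int, frozenset[str]]:
        sets: dict[int, frozenset[str]] = {}
        for v in self.postorder():
            if not self.children[v]:
                sets[v] = frozenset([self.labels[v]])
            else:
                s: set[str] = set()
                for c in self.children[v]:
                    s |= sets[c]
                sets[v] = frozenset(s)
        if not include_leaves:
            sets = {v: s for v, s in sets.items() if self.children[v]}
        return sets

    def clades(self) -> set[frozenset[str]]:
        """Resolved rooted clades: leaf sets of internal nodes, excluding
        the full taxon set."""
        full = self.taxa
        return {s for v, s in self.clade_leafsets().items() if s != full}

    # -- I/O ------------------------------------------------------------
    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if not self.children[v]:
                core = _quote(self.labels[v])
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
                if v in self.node_names:
                    core += _quote(self.node_names[v])
            if v == self.root:
                return core
            return f"{core}:{self.lengths[v]:.10g}"

        return rec(self.root) + ";"

    def copy(self) -> "RootedTree":
        return RootedTree(
            self.parent.copy(), self.lengths.copy(),
            [list(c) for c in self.children], dict(self.labels),
            self.root, dict(self.node_names),
        )


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    labels: dict[int, str] = {}
    names: dict[int, str] = {}
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else (nd.label or "")
            labels[i] = lab
        elif nd.taxon is not None or nd.label:
            names[i] = nd.taxon.label if nd.taxon is not None else nd.label
    return RootedTree(parent, lengths, children, labels, 0, names)


def read_newick(text: str) -> RootedTree:
    """Parse one rooted newick tree; missing branch lengths become 0."""
    text = text.strip()
    if text.count("(") != text.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"newick parse failed: {exc}") from exc
    tree = _from_dendropy(dtree)
    return tree


@dataclass
class TreeSample:
    """Ordered list of rooted trees over one shared taxon set."""

    trees: list[RootedTree]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trees:
            taxa = self.trees[0].taxa
            for i, t in enumerate(self.trees):
                if t.taxa != taxa:
                    raise ValueError(
                        f"tree {i} taxon set differs from tree 0: "
                        f"{sorted(t.taxa ^ taxa)}")

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> RootedTree:
        return self.trees[i]

    @property
    def taxa(self) -> frozenset[str]:
        return self.trees[0].taxa if self.trees else frozenset()

    def to_newick(self) -> str:
        return "\n".join(t.to_newick() for t in self.trees) + "\n"


def read_newick_sample(text: str, provenance: dict | None = None) -> TreeSample:
    """Read a newline-separated newick tree sample."""
    trees = [read_newick(line) for line in text.splitlines() if line.strip()]
    return TreeSample(trees, provenance or {})


# ---------------------------------------------------------------------------
# operations


def prune_to_taxa(tree: RootedTree, keep: Iterable[str]) -> RootedTree:
    """Restrict a tree to ``keep``, collapsing unary nodes (lengths summed).

    Pairwise path lengths among the kept taxa are unchanged.
    """
    keep = set(keep)
    unknown = keep - tree.taxa
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")

    # mark nodes on paths to kept leaves
    keep_node = np.zeros(tree.n_nodes, dtype=bool)
    for v in tree.postorder():
        if not tree.children[v]:
            keep_node[v] = tree.labels[v] in keep
        else:
            keep_node[v] = any(keep_node[c] for c in tree.children[v])

    # rebuild, collapsing unary internals
    new_parent: list[int] = []
    new_len: list[float] = []
    new_children: list[list[int]] = []
    new_labels: dict[int, str] = {}

    def build(v: int, acc_len: float, parent_new: int) -> None:
        kids = [c for c in tree.children[v] if keep_node[c]]
        is_leaf = not tree.children[v]
        if not is_leaf and len(kids) == 1 and parent_new != -2:
            # unary internal: collapse into the single child
            build(kids[0], acc_len + tree.lengths[kids[0]], parent_new)
            return
        if not is_leaf and len(kids) == 1 and parent_new == -2:
            # unary root: child becomes root
            build(kids[0], 0.0, -2)
            return
        idx = len(new_parent)
        new_parent.append(parent_new if parent_new >= 0 else -1)
        new_len.append(acc_len if parent_new >= 0 else 0.0)
        new_children.append([])
        if parent_new >= 0:
            new_children[parent_new].append(idx)
        if is_leaf:
            new_labels[idx] = tree.labels[v]
        for c in kids:
            build(c, tree.lengths[c], idx)

    build(tree.root, 0.0, -2)
    return RootedTree(np.array(new_parent), np.array(new_len),
                      new_children, new_labels, 0)


def is_ultrametric(tree: RootedTree, rel_tolerance: float = 1e-6) -> bool:
    """True iff all root-to-leaf path lengths agree to ``rel_tolerance``."""
    d = tree.depths()
    leaf_d = np.array([d[v] for v in tree.leaves()])
    mx = leaf_d.max()
    if mx == 0:
        return True
    return bool(leaf_d.max() - leaf_d.min() <= rel_tolerance * mx)


def satisfies_backbone(tree: RootedTree, constraint: RootedTree) -> bool:
    """True iff every resolved clade of the constraint, restricted to the
    shared taxa, is a clade of ``tree``.

    The constraint may contain polytomies; its branch lengths are ignored.
    """
    shared = constraint.taxa & tree.taxa
    if not constraint.taxa <= tree.taxa:
        raise ValueError("constraint taxa must be a subset of tree taxa")
    tree_restricted = {ls & shared for ls in tree.clade_leafsets().values()}
    full = constraint.taxa
    for cl in constraint.clades():
        if cl == full:
            continue
        cl = cl & shared
        if len(cl) < 2:
            continue
        if cl not in tree_restricted:
            return False
    return True


def filter_by_backbone(sample: TreeSample, constraint: RootedTree) -> TreeSample:
    """Subsample (order preserved) of the trees compatible with the backbone."""
    kept = [t for t in sample if satisfies_backbone(t, constraint)]
    if not kept:
        warnings.warn("backbone filter removed every tree", stacklevel=2)
    prov = dict(sample.provenance)
    prov["backbone_filtered"] = {"input": len(sample), "kept": len(kept)}
    return TreeSample(kept, prov)


def max_clade_credibility(sample: TreeSample) -> tuple[RootedTree, dict[frozenset[str], float]]:
    """Member tree maximizing the product of its clades' sample frequencies.

    Ties break to the earliest tree in sample order.  Returns the tree and
    the clade -> frequency map over the whole sample.
    """
    if len(sample) == 0:
        raise ValueError("empty tree sample")
    counts: dict[frozenset[str], int] = {}
    per_tree: list[set[frozenset[str]]] = []
    for t in sample:
        cl = t.clades()
        per_tree.append(cl)
        for c in cl:
            counts[c] = counts.get(c, 0) + 1
    n = len(sample)
    freqs = {c: k / n for c, k in counts.items()}
    best_i, best_score = 0, -np.inf
    for i, cl in enumerate(per_tree):
        score = float(np.sum([np.log(freqs[c]) for c in cl])) if cl else 0.0
        if score > best_score:
            best_i, best_score = i, score
    return sample[best_i], freqs
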