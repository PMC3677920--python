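"""Synthetic trees and correlated/independent character data.

Generates everything the analysis consumes — posterior-like samples of
ultrametric trees and binary/3-state reproductive characters — with the
statistical structure the study system exhibits: 29 taxa (25 ingroup +
4 outgroup), mostly-concordant penis-sac (S) and pregenital-barrier (B)
states with rare discordant taxa, and a male 3-state character whose
enhanced-pedipalp state (P+) never co-occurs with penile sacs (S+).

Yule convention: the pure-birth process starts from the root split
(2 lineages) and stops at the n-th birth; tips extend to that last
event time, so the expected root height is sum_{k=2}^{n-1} 1/(lambda k).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .characters import CharacterData, combine_binary
from .likelihood import CharacterHistory, simulate_character
from .ratemodels import (DEP_8RATE, MALE_2RATE, RateModelSpec, RootPolicy,
                         build_generator, joint_embedding)
from .trees import RootedTree, TreeSample

__all__ = [
    "ScenarioConfig", "simulate_yule_tree", "simulate_tree_sample",
    "simulate_dataset", "make_study_like_fixture", "SyntheticDataset",
    "scenario_generator",
]

S_STATES = ("S+", "S-")
B_STATES = ("B-", "B+")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror the empirical design: 29 taxa of which 4 are
    outgroup, a posterior-like sample of ultrametric trees (unit root
    height), and scenario-specific transition rates on that time scale.
    """

    n_taxa: int = 29
    n_outgroup: int = 4
    birth_rate: float = 1.0
    n_trees: int = 100
    scenario: str = "DEPENDENT"   # INDEPENDENT | DEPENDENT | PRECEDENCE | MALE_CHAIN
    base_rate: float = 1.0        # per-unit-height transition rate
    coupling: float = 5.0         # dependent-scenario speedup into concordant states
    precedence: float = 10.0      # sac-loss vs barrier-gain rate ratio (PRECEDENCE)
    pedipalp_gain_rate: float = 1.0
    jitter_sigma: float = 0.1     # lognormal branch-length spread across the sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if not (0 < self.n_outgroup < self.n_taxa):
            raise ValueError("outgroup size must be in (0, n_taxa)")
        if min(self.birth_rate, self.base_rate, self.coupling,
               self.precedence, self.pedipalp_gain_rate) <= 0:
            raise ValueError("rates must be positive")
        if self.scenario not in {"INDEPENDENT", "DEPENDENT", "PRECEDENCE",
                                 "MALE_CHAIN"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")


def simulate_yule_tree(n_taxa: int, birth_rate: float,
                       seed: int | np.random.Generator = 0,
                       labels: list[str] | None = None) -> RootedTree:
    """Ultrametric binary pure-birth tree with ``n_taxa`` leaves.

    Waiting time between the k-th and (k+1)-th birth is Exp(lambda*k);
    the process stops at the n-th birth and all tips extend one further
    Exp(lambda*n) waiting time, so terminal branches are never
    zero-length.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = labels or [f"t{i + 1:02d}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("label count must equal n_taxa")

    # grow: active lineages carry their birth times
    birth_time = {0: 0.0, 1: 0.0}
    children: dict[int, list[int]] = {-1: [0, 1]}
    parent = {0: -1, 1: -1}
    active = [0, 1]
    t = 0.0
    next_id = 2
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        split = active[int(rng.integers(k))]
        a, b = next_id, next_id + 1
        next_id += 2
        parent[a] = parent[b] = split
        children[split] = [a, b]
        birth_time[a] = birth_time[b] = t
        active.remove(split)
        active.extend([a, b])
    # tips extend one further waiting time beyond the n-th birth (the
    # time at which the (n+1)-th birth would occur), so no terminal
    # branch has zero length; expected height is
    # sum_{k=2}^{n-1} 1/(lambda k) + 1/(lambda n)
    T = t + rng.exponential(1.0 / (birth_rate * n_taxa))

    # relabel into contiguous array form (preorder from the root -1)
    n_nodes = len(parent) + 1
    pre = []
    stack = [-1]
    while stack:
        v = stack.pop()
        pre.append(v)
        for c in children.get(v, []):
            stack.append(c)
    remap = {v: i for i, v in enumerate(pre)}
    par = np.full(n_nodes, -1, dtype=int)
    lens = np.zeros(n_nodes)
    chl: list[list[int]] = [[] for _ in range(n_nodes)]
    labs: dict[int, str] = {}
    leaf_i = 0
    for v in pre:
        i = remap[v]
        if v != -1:
            p = parent[v]
            par[i] = remap[p]
            chl[remap[p]].append(i)
            end = T if v in active else birth_time[children[v][0]]
            lens[i] = end - birth_time[v]
        if v in active:
            labs[i] = labels[leaf_i]
            leaf_i += 1
    return RootedTree(par, lens, chl, labs, 0)


def _scale_to_height(tree: RootedTree, height: float = 1.0) -> RootedTree:
    d = tree.depths()
    h = max(d[v] for v in tree.leaves())
    t = tree.copy()
    if h > 0:
        t.lengths = t.lengths * (height / h)
    return t


def _join_with_outgroup(ingroup: RootedTree, outgroup: RootedTree,
                        stem_fraction: float = 0.2) -> RootedTree:
    """Root with the ingroup and outgroup as the two children, both
    extended by stems to a common height."""
    hi = max(ingroup.depths()[v] for v in ingroup.leaves())
    ho = max(outgroup.depths()[v] for v in outgroup.leaves())
    H = max(hi, ho) * (1 + stem_fraction)
    n_i, n_o = ingroup.n_nodes, outgroup.n_nodes
    n = 1 + n_i + n_o
    par = np.full(n, -1, dtype=int)
    lens = np.zeros(n)
    chl: list[list[int]] = [[] for _ in range(n)]
    labs: dict[int, str] = {}
    for off, sub, h in ((1, ingroup, hi), (1 + n_i, outgroup, ho)):
        for v in range(sub.n_nodes):
            if sub.parent[v] < 0:
                par[off + v] = 0
                chl[0].append(off + v)
                lens[off + v] = H - h
            else:
                par[off + v] = off + sub.parent[v]
                chl[off + sub.parent[v]].append(off + v)
                lens[off + v] = sub.lengths[v]
            if v in sub.labels:
                labs[off + v] = sub.labels[v]
    return RootedTree(par, lens, chl, labs, 0)


def _sample_labels(config: ScenarioConfig) -> tuple[list[str], list[str]]:
    n_in = config.n_taxa - config.n_outgroup
    return ([f"in{i + 1:02d}" for i in range(n_in)],
            [f"out{i + 1:02d}" for i in range(config.n_outgroup)])


def simulate_tree_sample(config: ScenarioConfig) -> TreeSample:
    """Posterior-like sample: independent outgroup-rooted Yule trees on one
    label set, unit root height, optional lognormal branch-length jitter."""
    rng = np.random.default_rng(config.seed)
    in_labels, out_labels = _sample_labels(config)
    trees = []
    for _ in range(config.n_trees):
        ing = simulate_yule_tree(len(in_labels), config.birth_rate, rng, in_labels)
        if len(out_labels) >= 2:
            outg = simulate_yule_tree(len(out_labels), config.birth_rate, rng,
                                      out_labels)
            tree = _join_with_outgroup(ing, outg)
        else:
            tree = ing
        tree = _scale_to_height(tree, 1.0)
        if config.jitter_sigma > 0:
            tree.lengths = tree.lengths * rng.lognormal(
                0.0, config.jitter_sigma, size=tree.n_nodes)
            tree.lengths[tree.root] = 0.0
        trees.append(tree)
    return TreeSample(trees, {"source": "yule", "config": config.scenario,
                              "seed": config.seed})


def scenario_generator(config: ScenarioConfig) -> tuple[RateModelSpec, np.ndarray]:
    """Rate-model spec and true rate vector implied by a scenario."""
    r = config.base_rate
    if config.scenario == "INDEPENDENT":
        s_spec = RateModelSpec("s_binary", S_STATES,
                               ((-1, 0), (1, -1)))
        b_spec = RateModelSpec("b_binary", B_STATES,
                               ((-1, 0), (1, -1)))
        spec = joint_embedding(s_spec, b_spec, name="indep_scenario")
        rates = np.array([r, r, r, r])
    elif config.scenario == "DEPENDENT":
        spec = DEP_8RATE
        c = config.coupling
        # transitions into concordant states (S+B- = 0, S-B+ = 2) are c-fold faster
        rates = np.empty(8)
        targets = {0: 1, 1: 3, 2: 0, 3: 2, 4: 1, 5: 3, 6: 0, 7: 2}
        for slot, tgt in targets.items():
            rates[slot] = r * c if tgt in (0, 2) else r
    elif config.scenario == "PRECEDENCE":
        spec = DEP_8RATE
        rates = np.full(8, r)
        rates[1] = r * config.precedence   # sac loss S+B- -> S-B- much faster
        rates[0] = r                       # than barrier gain S+B- -> S+B+
    else:  # MALE_CHAIN
        spec = MALE_2RATE
        rates = np.array([r, r])
    return spec, rates


@dataclass
class SyntheticDataset:
    """Trees plus the three character matrices and their true histories."""

    trees: TreeSample
    char_s: CharacterData
    char_b: CharacterData
    char_male: CharacterData
    history_s: CharacterHistory | None = None
    history_b: CharacterHistory | None = None
    truth: dict = field(default_factory=dict)

    @property
    def char_joint(self) -> CharacterData:
        return combine_binary(self.char_s, self.char_b)


def _overlay_pedipalps(hist_s: CharacterHistory, gain_rate: float,
                       rng: np.random.Generator) -> CharacterData:
    """Male 3-state character from the S history plus an independent
    pedipalp (P) overlay that can only switch on while sacs are absent.

    P resets to simple (P-) whenever sacs are present, so S+P+ never
    occurs.  States: (S+P-, S-P-, S-P+).
    """
    tree = hist_s.tree
    p_state = np.zeros(tree.n_nodes, dtype=int)
    for v in reversed(tree.postorder()):
        if v == tree.root:
            p_state[v] = 0
            continue
        p = int(p_state[tree.parent[v]])
        for s, ln in hist_s.segments[v]:
            if s == 0:          # sacs present: enhanced pedipalps not maintained
                p = 0
            elif p == 0 and ln > 0:
                if rng.uniform() < 1.0 - np.exp(-gain_rate * ln):
                    p = 1
        p_state[v] = p
    labels = {}
    for v in tree.leaves():
        s = int(hist_s.node_states[v])
        m = 0 if s == 0 else (2 if p_state[v] == 1 else 1)
        labels[tree.labels[v]] = ("S+P-", "S-P-", "S-P+")[m]
    return CharacterData.from_labels(("S+P-", "S-P-", "S-P+"), labels)


def simulate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Tree sample plus S, B and male 3-state characters evolved under the
    scenario's generator on the first tree of the sample."""
    rng = np.random.default_rng(config.seed + 1)
    trees = simulate_tree_sample(config)
    tree = trees[0]
    spec, rates = scenario_generator(config)
    Q = build_generator(spec, rates)
    truth: dict = {"scenario": config.scenario, "spec": spec.name,
                   "rates": [float(x) for x in rates]}

    if config.scenario == "MALE_CHAIN":
        root = RootPolicy.fixed(0)
        male, hist = simulate_character(tree, Q, root, rng,
                                        state_space=list(spec.state_space))
        s_labels = {tx: ("S+" if male.assignments[tx] == 0 else "S-")
                    for tx in male.taxa}
        char_s = CharacterData.from_labels(S_STATES, s_labels)
        char_b = CharacterData.from_labels(
            B_STATES, {tx: "B-" for tx in male.taxa})
        truth["n_changes"] = {"male": hist.n_changes()}
        return SyntheticDataset(trees, char_s, char_b, male,
                                history_s=hist, truth=truth)

    root = RootPolicy.fixed(0)  # ancestral S+B-
    joint, hist = simulate_character(tree, Q, root, rng,
                                     state_space=list(spec.state_space))
    # split the joint history into marginal S and B histories
    s_hist, b_hist = _split_joint_history(hist)
    char_s = s_hist.tip_data(list(S_STATES))
    char_b = b_hist.tip_data(list(B_STATES))
    male = _overlay_pedipalps(s_hist, config.pedipalp_gain_rate, rng)
    truth["n_changes"] = {"S": s_hist.n_changes(), "B": b_hist.n_changes()}
    return SyntheticDataset(trees, char_s, char_b, male,
                            history_s=s_hist, history_b=b_hist, truth=truth)


_JOINT_TO_S = {0: 0, 1: 0, 2: 1, 3: 1}   # S+B-, S+B+, S-B+, S-B-
_JOINT_TO_B = {0: 0, 1: 1, 2: 1, 3: 0}


def _split_joint_history(hist: CharacterHistory,
                         ) -> tuple[CharacterHistory, CharacterHistory]:
    from .likelihood import _merge_zero_segments
    tree = hist.tree
    s_states = np.array([_JOINT_TO_S[int(s)] for s in hist.node_states])
    b_states = np.array([_JOINT_TO_B[int(s)] for s in hist.node_states])
    s_segs, b_segs = {}, {}
    for v, segs in hist.segments.items():
        s_segs[v] = _merge_zero_segments([(_JOINT_TO_S[s], ln) for s, ln in segs])
        b_segs[v] = _merge_zero_segments([(_JOINT_TO_B[s], ln) for s, ln in segs])
    return (CharacterHistory(tree, s_states, s_segs),
            CharacterHistory(tree, b_states, b_segs))


# ---------------------------------------------------------------------------
# hard-coded 29-taxon fixture

_FIXTURE_TOPOLOGY = (
    (
        (
            ("early01", "early02", ("early03", "early04"), ("early05", "early06")),
            ("calcar", "hoffmani", ("nigropalpi", ("uxorium", "sp_NE"))),
        ),
        (
            (
                (("vittatum", "sp_TN"), ("euserratipalpe", "relictum")),
                ("speciosum", "cupreum"),
            ),
            (
                (("nigripes", "bracchiolum"), "crassipalpe"),
                (
                    "bimaculatum",
                    (("grandis", "sp3_IL"), ("maculosus", "davisi")),
                ),
            ),
        ),
    ),
    ("west01", ("west02", ("west03", "west04"))),
)

_FIXTURE_STATES = {
    # early-season sacculate clade and other sacculate ingroup taxa
    **{t: ("S+", "B-", "S+P-") for t in
       ("early01", "early02", "early03", "early04", "early05", "early06",
        "speciosum", "cupreum", "bimaculatum")},
    # outgroup: ancestral syndrome
    **{t: ("S+", "B-", "S+P-") for t in ("west01", "west02", "west03", "west04")},
    # vittatum group: antagonistic, enhanced pedipalps; relictum lacks both
    "vittatum": ("S-", "B+", "S-P+"),
    "sp_TN": ("S-", "B+", "S-P+"),
    "euserratipalpe": ("S-", "B+", "S-P+"),
    "relictum": ("S-", "B-", "S-P-"),
    # calcar group: antagonistic, enhanced pedipalps
    "calcar": ("S-", "B+", "S-P+"),
    "hoffmani": ("S-", "B+", "S-P+"),
    "nigropalpi": ("S-", "B+", "S-P+"),
    "uxorium": ("S-", "B+", "S-P+"),
    "sp_NE": ("S-", "B+", "S-P+"),
    # nigripes group: non-sacculate, simple pedipalps
    "nigripes": ("S-", "B+", "S-P-"),
    "bracchiolum": ("S-", "B+", "S-P-"),
    "crassipalpe": ("S-", "B+", "S-P-"),
    # Hadrobunus-like group: two sacculate-with-barrier taxa, two losses
    "grandis": ("S+", "B+", "S+P-"),
    "sp3_IL": ("S+", "B+", "S+P-"),
    "maculosus": ("S-", "B+", "S-P-"),
    "davisi": ("S-", "B+", "S-P-"),
}


def _tree_from_nested(nested, height_decay: float = 0.75) -> RootedTree:
    """Ultrametric tree from nested tuples; internal node heights decay
    geometrically from a unit-height root."""
    par: list[int] = []
    lens: list[float] = []
    chl: list[list[int]] = []
    labs: dict[int, str] = {}

    def new_node(parent_i: int) -> int:
        i = len(par)
        par.append(parent_i)
        lens.append(0.0)
        chl.append([])
        if parent_i >= 0:
            chl[parent_i].append(i)
        return i

    def build(node, parent_i: int, parent_h: float, depth: int) -> None:
        i = new_node(parent_i)
        if isinstance(node, str):
            labs[i] = node
            lens[i] = parent_h
            return
        h = height_decay ** depth
        lens[i] = parent_h - h if parent_i >= 0 else 0.0
        for child in node:
            build(child, i, h, depth + 1)

    build(_FIXTURE_TOPOLOGY, -1, 1.0, 0)
    return RootedTree(np.array(par), np.array(lens), chl, labs, 0)


def make_study_like_fixture(seed: int = 0, n_trees: int = 1,
                            jitter_sigma: float = 0.0) -> SyntheticDataset:
    """Deterministic synthetic 29-taxon dataset shaped like the empirical one.

    This is a synthetic stand-in for the study's summary tree, not a
    transcription of it: the branching order is hard-coded to be
    biologically plausible and to satisfy every constraint the study
    reports in text — 25 ingroup + 4 outgroup taxa, exactly two taxa
    with both sacs and barriers, exactly one taxon lacking both,
    non-sacculate-with-barrier taxa in four separate clades, and a
    minimum of four Dollo sac losses and four barrier gains.
    """
    base = _tree_from_nested(_FIXTURE_TOPOLOGY)
    rng = np.random.default_rng(seed)
    trees = [base]
    for _ in range(n_trees - 1):
        t = base.copy()
        if jitter_sigma > 0:
            t.lengths = t.lengths * rng.lognormal(0.0, jitter_sigma, t.n_nodes)
            t.lengths[t.root] = 0.0
        trees.append(t)
    sample = TreeSample(trees, {"source": "synthetic_fixture", "seed": seed})
    taxa = sorted(_FIXTURE_STATES)
    char_s = CharacterData.from_labels(S_STATES,
                                       {t: _FIXTURE_STATES[t][0] for t in taxa})
    char_b = CharacterData.from_labels(B_STATES,
                                       {t: _FIXTURE_STATES[t][1] for t in taxa})
    char_m = CharacterData.from_labels(("S+P-", "S-P-", "S-P+"),
                                       {t: _FIXTURE_STATES[t][2] for t in taxa})
    return SyntheticDataset(sample, char_s, char_b, char_m,
                            truth={"scenario": "FIXTURE"})
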