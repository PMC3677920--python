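"""Constrained k-state generator-matrix templates for trait evolution.

A :class:`RateModelSpec` encodes which directed transitions are allowed
and which share a rate parameter.  The named constants cover the model
roster used for the harvestman reproductive-trait comparisons:

* ``MALE_6RATE``   -- 3 male states (S+P-, S-P-, S-P+), all 6 directed
  transitions free ("no precedence").
* ``MALE_2RATE``   -- only sac loss (S+P- -> S-P-) then pedipalp gain
  (S-P- -> S-P+) allowed ("penis precedence").
* ``INDEP_4RATE``  -- 4 joint penis/barrier states; each character's gain
  and loss rate shared across the state of the other character.
* ``DEP_8RATE``    -- all 8 single-step joint transitions free
  ("dependent, precedence-possible").
* ``DEP_7RATE_NOPREC`` -- DEP_8RATE with barrier gain (S+B- -> S+B+) and
  sac loss (S+B- -> S-B-) forced to one shared rate ("no precedence").

Joint states are ordered (S+B-, S+B+, S-B+, S-B-); dual transitions
(both characters changing at once) are structural zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "RootPolicy", "RateModelSpec", "build_generator", "joint_embedding",
    "model_df", "MALE_6RATE", "MALE_2RATE", "INDEP_4RATE", "DEP_8RATE",
    "DEP_7RATE_NOPREC",
]

ZERO = -1  # template entry: structurally forbidden transition


class RootPolicy:
    """Prior over the root state: UNIFORM, FIXED(state) or EMPIRICAL."""

    def __init__(self, kind: str, state: int | None = None):
        kind = kind.upper()
        if kind not in {"UNIFORM", "FIXED", "EMPIRICAL"}:
            raise ValueError(f"unknown root policy {kind!r}")
        if kind == "FIXED" and (state is None or state < 0):
            raise ValueError("FIXED root policy needs a state index")
        self.kind = kind
        self.state = state

    @classmethod
    def uniform(cls) -> "RootPolicy":
        return cls("UNIFORM")

    @classmethod
    def fixed(cls, state: int) -> "RootPolicy":
        return cls("FIXED", state)

    @classmethod
    def empirical(cls) -> "RootPolicy":
        return cls("EMPIRICAL")

    def pi(self, k: int, tip_frequencies: Sequence[float] | None = None) -> np.ndarray:
        if self.kind == "UNIFORM":
            return np.full(k, 1.0 / k)
        if self.kind == "FIXED":
            if self.state >= k:
                raise ValueError(f"fixed root state {self.state} >= k={k}")
            v = np.zeros(k)
            v[self.state] = 1.0
            return v
        if tip_frequencies is None:
            raise ValueError("EMPIRICAL root policy needs tip frequencies")
        return np.asarray(tip_frequencies, dtype=float)

    def __repr__(self) -> str:
        return f"RootPolicy({self.kind}{'' if self.state is None else ', ' + str(self.state)})"

    def __eq__(self, other) -> bool:
        return (isinstance(other, RootPolicy)
                and self.kind == other.kind and self.state == other.state)


@dataclass(frozen=True)
class RateModelSpec:
    """Template for a k-state CTMC generator with equality/zero constraints.

    ``template[i][j]`` for i != j is either ``ZERO`` or a parameter slot
    index in ``0..n_params-1``; shared indices express rate equality.
    The diagonal is implied (negative row sums).
    """

    name: str
    state_space: tuple[str, ...]
    template: tuple[tuple[int, ...], ...]
    root_policy: RootPolicy = field(default_factory=RootPolicy.uniform)

    def __post_init__(self) -> None:
        k = self.k
        if len(self.template) != k or any(len(r) != k for r in self.template):
            raise ValueError("template must be k x k")
        slots = {e for i, row in enumerate(self.template)
                 for j, e in enumerate(row) if i != j and e != ZERO}
        if not slots:
            raise ValueError("model must have at least one free parameter")
        if slots != set(range(len(slots))):
            raise ValueError("parameter slots must be 0..n_params-1")
        if self.root_policy.kind == "FIXED" and self.root_policy.state >= k:
            raise ValueError("FIXED root state out of range")

    @property
    def k(self) -> int:
        return len(self.state_space)

    @property
    def n_params(self) -> int:
        return 1 + max(e for i, row in enumerate(self.template)
                       for j, e in enumerate(row) if i != j and e != ZERO)

    def with_root(self, policy: RootPolicy) -> "RateModelSpec":
        return RateModelSpec(self.name, self.state_space, self.template, policy)

    def to_config(self) -> dict:
        return {
            "name": self.name,
            "states": list(self.state_space),
            "template": [list(r) for r in self.template],
            "root_policy": {"kind": self.root_policy.kind,
                            "state": self.root_policy.state},
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "RateModelSpec":
        rp = cfg.get("root_policy", {"kind": "UNIFORM", "state": None})
        return cls(cfg["name"], tuple(cfg["states"]),
                   tuple(tuple(r) for r in cfg["template"]),
                   RootPolicy(rp["kind"], rp.get("state")))


def build_generator(spec: RateModelSpec, rates: Sequence[float]) -> np.ndarray:
    """Instantiate the generator matrix Q from a rate vector.

    Off-diagonals are filled from the template; the diagonal makes every
    row sum to zero.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (spec.n_params,):
        raise ValueError(
            f"expected {spec.n_params} rates, got {rates.shape}")
    if np.any(rates <= 0):
        raise ValueError("rates must be strictly positive")
    k = spec.k
    Q = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i != j and spec.template[i][j] != ZERO:
                Q[i, j] = rates[spec.template[i][j]]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def joint_embedding(spec_a: RateModelSpec, spec_b: RateModelSpec,
                    name: str | None = None) -> RateModelSpec:
    """Embed two binary models into one 4-state joint model.

    The joint chain changes one character at a time at that character's
    own rate, so its likelihood factorizes exactly into the product of
    the two marginal likelihoods.  Parameter slots of the second model
    are offset by the first model's parameter count.  Joint state order
    is (a0 b0, a0 b1, a1 b1, a1 b0).
    """
    if spec_a.k != 2 or spec_b.k != 2:
        raise ValueError("joint embedding requires two binary models")
    off = spec_a.n_params
    joint_states = (
        f"{spec_a.state_space[0]}{spec_b.state_space[0]}",
        f"{spec_a.state_space[0]}{spec_b.state_space[1]}",
        f"{spec_a.state_space[1]}{spec_b.state_space[1]}",
        f"{spec_a.state_space[1]}{spec_b.state_space[0]}",
    )
    joint_to_pair = {0: (0, 0), 1: (0, 1), 2: (1, 1), 3: (1, 0)}

    def slot(i: int, j: int) -> int:
        sa, sb = joint_to_pair[i]
        ta, tb = joint_to_pair[j]
        if sa != ta and sb == tb:
            e = spec_a.template[sa][ta]
            return ZERO if e == ZERO else e
        if sb != tb and sa == ta:
            e = spec_b.template[sb][tb]
            return ZERO if e == ZERO else e + off
        return ZERO  # dual transition

    template = tuple(tuple(slot(i, j) if i != j else 0 for j in range(4))
                     for i in range(4))
    # fix diagonal placeholders: mark as ZERO (diagonal ignored by contract)
    template = tuple(tuple(ZERO if i == j else template[i][j] for j in range(4))
                     for i in range(4))
    return RateModelSpec(name or f"indep({spec_a.name},{spec_b.name})",
                         joint_states, template)


def model_df(complex_spec: RateModelSpec, simple_spec: RateModelSpec) -> int:
    """Degrees of freedom for a nested comparison: difference in free
    rate-parameter counts."""
    d = complex_spec.n_params - simple_spec.n_params
    if d < 0:
        raise ValueError(
            f"{complex_spec.name} has fewer parameters than {simple_spec.name}")
    return d


def _tpl(k: int, entries: dict[tuple[int, int], int]) -> tuple[tuple[int, ...], ...]:
    return tuple(tuple(entries.get((i, j), ZERO) if i != j else ZERO
                       for j in range(k)) for i in range(k))


MALE_STATES = ("S+P-", "S-P-", "S-P+")
JOINT_STATES = ("S+B-", "S+B+", "S-B+", "S-B-")

MALE_6RATE = RateModelSpec(
    "male_6rate", MALE_STATES,
    _tpl(3, {(0, 1): 0, (1, 0): 1, (1, 2): 2, (2, 1): 3, (0, 2): 4, (2, 0): 5}),
)

MALE_2RATE = RateModelSpec(
    "male_2rate", MALE_STATES,
    _tpl(3, {(0, 1): 0, (1, 2): 1}),
)

# single-step joint moves: 0<->1 (barrier), 1<->2 (sacs), 2<->3 (barrier),
# 3<->0 (sacs); dual moves 0<->2, 1<->3 are structural zeros.
INDEP_4RATE = RateModelSpec(
    "indep_4rate", JOINT_STATES,
    _tpl(4, {
        (0, 3): 0, (1, 2): 0,   # sac loss, shared over barrier state
        (3, 0): 1, (2, 1): 1,   # sac gain
        (0, 1): 2, (3, 2): 2,   # barrier gain, shared over sac state
        (1, 0): 3, (2, 3): 3,   # barrier loss
    }),
)

DEP_8RATE = RateModelSpec(
    "dep_8rate", JOINT_STATES,
    _tpl(4, {
        (0, 1): 0, (0, 3): 1, (1, 0): 2, (1, 2): 3,
        (2, 1): 4, (2, 3): 5, (3, 0): 6, (3, 2): 7,
    }),
)

# barrier gain from the ancestral S+B- (0->1) and sac loss from it (0->3)
# share one rate; everything else free.
DEP_7RATE_NOPREC = RateModelSpec(
    "dep_7rate_noprec", JOINT_STATES,
    _tpl(4, {
        (0, 1): 0, (0, 3): 0, (1, 0): 1, (1, 2): 2,
        (2, 1): 3, (2, 3): 4, (3, 0): 5, (3, 2): 6,
    }),
)
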