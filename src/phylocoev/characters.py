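"""Categorical character matrices: taxon -> state, with a declared state space.

File format is tab-delimited with a ``taxon<TAB>state`` header; ``?``
codes a missing observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

MISSING = -1

__all__ = ["CharacterData", "MISSING", "read_character_tsv", "combine_binary"]


@dataclass
class CharacterData:
    """Mapping of taxa to categorical states over an ordered state space."""

    state_space: list[str]
    assignments: dict[str, int]  # taxon -> state index, MISSING for '?'

    def __post_init__(self) -> None:
        k = len(self.state_space)
        if k < 2:
            raise ValueError("state space needs at least 2 states")
        if len(set(self.state_space)) != k:
            raise ValueError("state labels must be unique")
        for taxon, s in self.assignments.items():
            if s != MISSING and not (0 <= s < k):
                raise ValueError(f"state index {s} for {taxon!r} out of range")

    @property
    def k(self) -> int:
        return len(self.state_space)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset(self.assignments)

    def state_of(self, taxon: str) -> int:
        return self.assignments[taxon]

    def label_of(self, taxon: str) -> str:
        s = self.assignments[taxon]
        return "?" if s == MISSING else self.state_space[s]

    def counts(self) -> list[int]:
        out = [0] * self.k
        for s in self.assignments.values():
            if s != MISSING:
                out[s] += 1
        return out

    def frequencies(self) -> list[float]:
        c = self.counts()
        tot = sum(c)
        if tot == 0:
            return [1.0 / self.k] * self.k
        return [x / tot for x in c]

    @classmethod
    def from_labels(cls, state_space: Sequence[str],
                    labelled: Mapping[str, str]) -> "CharacterData":
        index = {s: i for i, s in enumerate(state_space)}
        assignments = {}
        for taxon, lab in labelled.items():
            if lab == "?":
                assignments[taxon] = MISSING
            elif lab in index:
                assignments[taxon] = index[lab]
            else:
                raise ValueError(
                    f"unknown state {lab!r} for taxon {taxon!r}; "
                    f"state space is {list(state_space)}")
        return cls(list(state_space), assignments)

    def to_tsv(self) -> str:
        lines = ["taxon\tstate"]
        for taxon in sorted(self.assignments):
            lines.append(f"{taxon}\t{self.label_of(taxon)}")
        return "\n".join(lines) + "\n"


def read_character_tsv(text: str, state_space: Sequence[str] | None = None) -> CharacterData:
    """Read a ``taxon<TAB>state`` table.

    If ``state_space`` is omitted it is inferred from the observed labels
    in sorted order.
    """
    rows = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty character file")
    start = 1 if lines[0].lower().startswith("taxon") else 0
    for ln in lines[start:]:
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"bad character row: {ln!r}")
        rows.append((parts[0].strip(), parts[1].strip()))
    if state_space is None:
        observed = {lab for _, lab in rows if lab != "?"}
        state_space = _canonical_order(observed) or sorted(observed)
    return CharacterData.from_labels(state_space, dict(rows))


_CANONICAL_ORDERS = (
    ("S+", "S-"),
    ("B-", "B+"),
    ("S+P-", "S-P-", "S-P+"),
    ("S+B-", "S+B+", "S-B+", "S-B-"),
)


def _canonical_order(observed: set[str]) -> tuple[str, ...] | None:
    """Domain state orders (sacs, barrier, male, joint) recognized so that
    inferred state spaces match the package's conventions."""
    for order in _CANONICAL_ORDERS:
        if observed <= set(order):
            return order
    return None


def combine_binary(a: CharacterData, b: CharacterData,
                   joint_space: Sequence[str] | None = None) -> CharacterData:
    """Combine two binary characters into the 4-state joint character.

    Joint state order is ((a0,b0), (a0,b1), (a1,b1), (a1,b0)) so that
    every single-step transition changes exactly one underlying character
    between cyclically adjacent joint states.  A missing value in either
    character makes the joint state missing.
    """
    if a.k != 2 or b.k != 2:
        raise ValueError("both characters must be binary")
    if a.taxa != b.taxa:
        raise ValueError("characters must cover the same taxa")
    if joint_space is None:
        joint_space = [
            f"{a.state_space[0]}{b.state_space[0]}",
            f"{a.state_space[0]}{b.state_space[1]}",
            f"{a.state_space[1]}{b.state_space[1]}",
            f"{a.state_space[1]}{b.state_space[0]}",
        ]
    pair_to_joint = {(0, 0): 0, (0, 1): 1, (1, 1): 2, (1, 0): 3}
    assignments = {}
    for taxon in a.taxa:
        sa, sb = a.assignments[taxon], b.assignments[taxon]
        if sa == MISSING or sb == MISSING:
            assignments[taxon] = MISSING
        else:
            assignments[taxon] = pair_to_joint[(sa, sb)]
    return CharacterData(list(joint_space), assignments)
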