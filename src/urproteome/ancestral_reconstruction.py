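"""Ancestral state reconstruction and root-branch change tracing.

For ordered characters every node's set of most-parsimonious-reconstruction
(MPR) states is an interval ``[lo, hi]``: a state belongs to it iff some
full assignment of that state at the node achieves the minimal tree length.
Root-branch changes are read off the MPR interval of the root-adjacent node
(the crown): with a zero-state hypothetical ancestor, a character is gained
on the root branch iff the crown interval admits a state above the ancestor
state, and the gain is *ambiguous* iff the interval also admits the ancestor
state itself — the change can then be deferred to deeper branches at equal
cost (the accelerated/delayed-transformation disagreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tree import Node
from .character_coding import CharacterMatrix
from .parsimony_engine import (
    RootedTree,
    _dt,
    _sankoff_down,
    _sankoff_up,
    rooted_rows,
)


@dataclass
class RootChangeRecord:
    """Per-character change on the root branch of a Lundberg-rooted tree.

    ``crown_lo``/``crown_hi`` record the MPR interval at the root-adjacent
    node so the direction of an ambiguous change (steps = 0) stays explicit.
    """

    character_id: str
    gain_steps: int
    loss_steps: int
    ambiguous: bool
    crown_lo: int
    crown_hi: int
    ancestor_state: int

    @property
    def is_gain(self) -> bool:
        return self.crown_hi > self.ancestor_state

    @property
    def is_loss(self) -> bool:
        return self.crown_lo < self.ancestor_state


@dataclass
class PlesiomorphicSet:
    """Characters positioned at the root branch, with ambiguity flags."""

    members: set[str]
    ambiguous: set[str]

    def unambiguous(self) -> set[str]:
        return self.members - self.ambiguous

    def __len__(self) -> int:
        return len(self.members)


def mpr_intervals(
    rt: RootedTree, cm: CharacterMatrix
) -> dict[int, np.ndarray]:
    """MPR state intervals per node.

    Returns ``{id(node): array of shape (n_chars, 2)}`` with columns
    ``[lo, hi]``; every state in the interval is attainable in some
    most-parsimonious assignment.  Leaf intervals are their observed states.
    """
    rows = rooted_rows(rt, cm)
    tree = rt.tree
    D = _sankoff_down(tree, rows, cm.n_states)
    U = _sankoff_up(tree, D, cm.n_states)
    L = D[id(tree.root)].min(axis=0)  # per-character optimum
    out: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        total = D[id(node)] + U[id(node)]  # (S, C)
        optimal = total == L[None, :]
        S = cm.n_states
        states = np.arange(S)[:, None]
        lo = np.where(optimal, states, S).min(axis=0)
        hi = np.where(optimal, states, -1).max(axis=0)
        out[id(node)] = np.stack([lo, hi], axis=1).astype(np.int16)
    return out


def root_branch_changes(
    rt: RootedTree, cm: CharacterMatrix
) -> list[RootChangeRecord]:
    """Gains/losses on the branch from the hypothetical ancestor to the crown.

    A character is recorded when the crown MPR interval admits a state that
    differs from the ancestor state.  ``gain_steps`` is the guaranteed
    minimum increase (interval lower bound minus ancestor state) and is zero
    for ambiguous gains; with a zero-state ancestor no losses can occur.
    """
    intervals = mpr_intervals(rt, cm)
    crown = intervals[id(rt.crown)]
    anc = rt.ancestor_state
    records: list[RootChangeRecord] = []
    for j, char in enumerate(cm.characters):
        lo, hi = int(crown[j, 0]), int(crown[j, 1])
        allows_anc = lo <= anc <= hi
        gain = hi > anc
        loss = lo < anc
        if not gain and not loss:
            continue
        records.append(
            RootChangeRecord(
                character_id=char,
                gain_steps=max(lo - anc, 0) if gain else 0,
                loss_steps=max(anc - hi, 0) if loss else 0,
                ambiguous=allows_anc,
                crown_lo=lo,
                crown_hi=hi,
                ancestor_state=anc,
            )
        )
    return records


def plesiomorphic_set(
    records: list[RootChangeRecord], mode: str = "acctran"
) -> PlesiomorphicSet:
    """Characters gained on the root branch.

    ``mode="acctran"`` (default) keeps ambiguous gains, flagged — changes are
    accelerated toward the root; ``mode="deltran"`` keeps only unambiguous
    gains (changes delayed away from the root).
    """
    if mode not in ("acctran", "deltran"):
        raise ValueError(f"unknown mode {mode!r}")
    gains = [r for r in records if r.is_gain]
    ambiguous = {r.character_id for r in gains if r.ambiguous}
    if mode == "deltran":
        gains = [r for r in gains if not r.ambiguous]
        ambiguous = set()
    return PlesiomorphicSet(members={r.character_id for r in gains}, ambiguous=ambiguous)


def changes_report(rt: RootedTree, cm: CharacterMatrix) -> list[dict]:
    """TSV-ready rows: character, gain, loss, ambiguous, interval at crown."""
    return [
        {
            "character": rec.character_id,
            "gain_steps": rec.gain_steps,
            "loss_steps": rec.loss_steps,
            "ambiguous": rec.ambiguous,
            "crown_lo": rec.crown_lo,
            "crown_hi": rec.crown_hi,
        }
        for rec in root_branch_changes(rt, cm)
    ]
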