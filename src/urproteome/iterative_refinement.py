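"""Iterative refinement of the root-branch (plesiomorphic) character set.

Characters gained on the root branch of a tree of proteomes include both
genuinely ancestral superfamilies and recent arrivals dragged to the root by
convergence and sampling ('the modern effect').  The refinement loop prunes
the latter: build trees on the current character set, extract the characters
positioned at the root branch, use them as the character set of the next
iteration, and repeat.  Several independent chains with different
random-addition seeds explore distinct parsimony islands; across everything
retained, the selected tree is the one with minimal length and, among those,
the smallest root set — its root set is the refined upper bound (max_set).

Per-iteration search seeds are derived from the chain seed *and* a digest of
the current character set, so reaching a fixed point (set unchanged between
iterations) provably freezes the chain: the same characters yield the same
search and the same root set.  Chains therefore stop at the first repeat,
rather than running a fixed patience window.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ancestral_reconstruction import (
    PlesiomorphicSet,
    plesiomorphic_set,
    root_branch_changes,
)
from .character_coding import CharacterMatrix
from .parsimony_engine import RootedTree, SearchConfig, lundberg_root, mp_search


@dataclass
class IterationRecord:
    iteration: int
    n_fsfs: int
    tree_length: int
    n_ambiguous: int
    fsf_set: frozenset[str]


@dataclass
class ChainTrace:
    chain_id: int
    initial_set: frozenset[str]
    iterations: list[IterationRecord] = field(default_factory=list)
    terminated: Optional[str] = None  # diagnostic when a chain dies early

    @property
    def final_set(self) -> frozenset[str]:
        return self.iterations[-1].fsf_set if self.iterations else self.initial_set


@dataclass
class RetainedTree:
    """One most-parsimonious tree kept for post-hoc selection."""

    chain_id: int
    iteration: int
    length: int
    root_set: PlesiomorphicSet
    rooted: RootedTree


@dataclass
class RefinementResult:
    traces: list[ChainTrace]
    retained: list[RetainedTree]
    max_set: set[str]
    selected: RetainedTree
    n_ties: int


def _set_seed(chain_seed: int, fsfs: frozenset[str]) -> int:
    digest = zlib.crc32(",".join(sorted(fsfs)).encode())
    return int(np.random.SeedSequence([chain_seed, digest]).generate_state(1)[0] % (2**31 - 1))


def run_chain(
    cm: CharacterMatrix,
    init_fsfs: set[str],
    n_iter: int = 50,
    cfg: Optional[SearchConfig] = None,
    seed: int = 0,
    chain_id: int = 0,
    combine: str = "union",
    collector: Optional[list[RetainedTree]] = None,
) -> ChainTrace:
    """One refinement chain: iterate (search -> root set -> restrict).

    ``combine`` merges root sets across equally parsimonious trees of one
    iteration (``"union"`` default, ``"intersection"`` available).  Retained
    trees are appended to ``collector`` when given.  Stops early at a fixed
    point or when the character set empties (diagnostic recorded).
    """
    if combine not in ("union", "intersection"):
        raise ValueError(f"unknown combine mode {combine!r}")
    base = cfg or SearchConfig(n_addition_replicates=2, swap="NNI")
    current = frozenset(init_fsfs)
    unknown = current - set(cm.characters)
    if unknown:
        raise ValueError(f"initial FSFs missing from the matrix: {sorted(unknown)[:5]}")
    trace = ChainTrace(chain_id=chain_id, initial_set=current)
    for it in range(1, n_iter + 1):
        if not current:
            trace.terminated = f"iteration {it}: empty character set"
            break
        sub = cm.restrict(current)
        it_cfg = SearchConfig(
            n_addition_replicates=base.n_addition_replicates,
            swap=base.swap,
            maxtrees=base.maxtrees,
            seed=_set_seed(seed, current),
            tbr_taxon_limit=base.tbr_taxon_limit,
        )
        trees = mp_search(sub, it_cfg)
        sets: list[PlesiomorphicSet] = []
        length = None
        for tree in trees:
            rt = lundberg_root(tree, sub)
            pset = plesiomorphic_set(root_branch_changes(rt, sub))
            sets.append(pset)
            length = rt.length if length is None else min(length, rt.length)
            if collector is not None:
                collector.append(
                    RetainedTree(
                        chain_id=chain_id,
                        iteration=it,
                        length=rt.length,
                        root_set=pset,
                        rooted=rt,
                    )
                )
        members = [s.members for s in sets]
        if combine == "union":
            new_set = frozenset(set().union(*members))
        else:
            new_set = frozenset(set.intersection(*members))
        ambiguous = set().union(*(s.ambiguous for s in sets)) & new_set
        trace.iterations.append(
            IterationRecord(
                iteration=it,
                n_fsfs=len(new_set),
                tree_length=int(length),
                n_ambiguous=len(ambiguous),
                fsf_set=new_set,
            )
        )
        if new_set == current:
            break  # fixed point: seeds derive from the set, nothing can change
        current = new_set
    return trace


def run_refinement(
    cm: CharacterMatrix,
    init_fsfs: set[str],
    n_chains: int = 30,
    n_iter: int = 50,
    cfg: Optional[SearchConfig] = None,
    seed: int = 0,
    combine: str = "union",
) -> RefinementResult:
    """Run all chains and select the tree defining the max_set.

    Chain seeds are spawned deterministically from the master seed.  The
    selection rule scans every retained most-parsimonious tree across all
    chains and iterations: minimal tree length first, then smallest root-set
    size; remaining ties are counted and broken by (chain, iteration) order.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    chain_seeds = [
        int(s % (2**31 - 1))
        for s in np.random.SeedSequence(seed).generate_state(n_chains)
    ]
    retained: list[RetainedTree] = []
    traces = [
        run_chain(
            cm,
            init_fsfs,
            n_iter=n_iter,
            cfg=cfg,
            seed=chain_seeds[c],
            chain_id=c,
            combine=combine,
            collector=retained,
        )
        for c in range(n_chains)
    ]
    if not retained:
        raise ValueError("no trees retained: all chains terminated immediately")
    key = lambda r: (r.length, len(r.root_set.members), r.chain_id, r.iteration)
    selected = min(retained, key=key)
    n_ties = sum(
        1
        for r in retained
        if r.length == selected.length
        and len(r.root_set.members) == len(selected.root_set.members)
    )
    return RefinementResult(
        traces=traces,
        retained=retained,
        max_set=set(selected.root_set.members),
        selected=selected,
        n_ties=n_ties,
    )
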