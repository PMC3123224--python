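"""Ordered-multistate (Wagner) maximum parsimony: scoring, search, rooting.

Characters are linearly ordered with unit step cost ``|i - j|`` between
states, matching abundance-derived characters where a change of one coded
abundance level costs one step.  Two exact scorers are used:

* a Farris interval pass (post-order min/max intervals) for binary trees —
  the fast path used inside tree search;
* a Sankoff dynamic program with linear step costs, evaluated over all states
  via a distance transform — the general path, which also yields per-edge
  insertion costs (for stepwise addition and Lundberg rooting) and per-node
  MPR state intervals.

Trees are rooted a posteriori by the Lundberg method: a hypothetical all-
ancestral-state taxon (all-0 or all-max depending on declared polarity) is
attached to the edge that minimizes total rooted length, without invoking any
outgroup.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
from scipy import stats

from ._tree import Node, Tree, star_tree
from .character_coding import CharacterMatrix

ANCESTOR_LABEL = "UR_ROOT"
_INF = np.int32(1 << 20)


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------


@dataclass
class SearchConfig:
    """Heuristic search settings.

    ``swap="TBR"`` performs true tree-bisection-reconnection only up to
    ``tbr_taxon_limit`` taxa and falls back to alternating SPR+NNI sweeps
    above it (the neighborhoods converge to the same optima on the matrix
    sizes this package targets, at a fraction of the cost).
    """

    n_addition_replicates: int = 4
    swap: str = "SPR"
    maxtrees: int = 50
    seed: Optional[int] = None
    tbr_taxon_limit: int = 12

    def __post_init__(self) -> None:
        if self.n_addition_replicates < 1:
            raise ValueError("n_addition_replicates must be >= 1")
        if self.swap.upper() not in ("NNI", "SPR", "TBR"):
            raise ValueError(f"unknown swap {self.swap!r}")
        self.swap = self.swap.upper()


@dataclass
class RootedTree:
    """A Lundberg-rooted tree.

    The hypothetical ancestor is a leaf labeled ``UR_ROOT`` attached as one
    child of the root; ``crown`` is the other child — the root-adjacent node
    on whose branch plesiomorphic changes are read.
    """

    tree: Tree
    crown: Node
    length: int
    unrooted_length: int
    ancestor_state: int
    n_states: int
    attachment_ties: int = 1

    @property
    def taxa(self) -> list[str]:
        return [t for t in self.tree.leaf_labels() if t != ANCESTOR_LABEL]


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _is_binary(tree: Tree) -> bool:
    for node in tree.postorder():
        if node.children and len(node.children) != 2:
            return False
    return True


def _leaf_rows(tree: Tree, rows: dict[str, np.ndarray]) -> None:
    for leaf in tree.leaves():
        if leaf.taxon not in rows:
            raise ValueError(f"leaf {leaf.taxon!r} has no character states")


def _farris_length(tree: Tree, rows: dict[str, np.ndarray]) -> tuple[int, np.ndarray]:
    """Exact length of ordered characters on a binary tree (Farris intervals)."""
    first = next(iter(rows.values()))
    ncols = first.shape[0]
    cost = np.zeros(ncols, dtype=np.int32)
    lo: dict[int, np.ndarray] = {}
    hi: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        key = id(node)
        if node.is_leaf:
            row = rows[node.taxon]
            lo[key] = row
            hi[key] = row
        else:
            c1, c2 = node.children
            l1, h1 = lo.pop(id(c1)), hi.pop(id(c1))
            l2, h2 = lo.pop(id(c2)), hi.pop(id(c2))
            nlo = np.maximum(l1, l2)
            nhi = np.minimum(h1, h2)
            gap = (nlo - nhi).astype(np.int32)
            disjoint = gap > 0
            if disjoint.any():
                cost += np.where(disjoint, gap, 0)
                nlo2 = np.where(disjoint, nhi, nlo)
                nhi2 = np.where(disjoint, nlo, nhi)
                nlo, nhi = nlo2, nhi2
            lo[key] = nlo
            hi[key] = nhi
    return int(cost.sum()), cost


def _dt(cost: np.ndarray) -> np.ndarray:
    """Distance transform along axis 0: out[s] = min_t cost[t] + |s - t|.

    Uses running minima of ``cost[t] - t`` and ``cost[t] + t`` so the
    transform costs O(S) numpy ops independent of the state count.
    """
    S = cost.shape[0]
    s = np.arange(S, dtype=cost.dtype).reshape((S,) + (1,) * (cost.ndim - 1))
    fwd = s + np.minimum.accumulate(cost - s, axis=0)
    bwd = -s + np.minimum.accumulate((cost + s)[::-1], axis=0)[::-1]
    return np.minimum(fwd, bwd)


def _leaf_cost(row: np.ndarray, n_states: int) -> np.ndarray:
    return np.abs(np.arange(n_states, dtype=np.int32)[:, None] - row[None, :]).astype(np.int32)


def _leaf_cost_hard(row: np.ndarray, n_states: int) -> np.ndarray:
    # 0 at the observed state, effectively infinite elsewhere: leaves are
    # fixed observations (their distance transform equals |s - obs|, so
    # lengths are unaffected, but MPR intervals at leaves stay points)
    out = np.full((n_states, row.shape[0]), _INF, dtype=np.int32)
    out[row, np.arange(row.shape[0])] = 0
    return out


def _sankoff_down(
    tree: Tree, rows: dict[str, np.ndarray], n_states: int
) -> dict[int, np.ndarray]:
    """Post-order cost tables D[v][s, c]: min cost of subtree v given state s."""
    D: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            D[id(node)] = _leaf_cost_hard(rows[node.taxon], n_states)
        else:
            acc = None
            for child in node.children:
                term = _dt(D[id(child)])
                acc = term if acc is None else acc + term
            D[id(node)] = acc
    return D


def _sankoff_up(
    tree: Tree, D: dict[int, np.ndarray], n_states: int
) -> dict[int, np.ndarray]:
    """Pre-order tables U[v][s, c]: min cost of everything outside subtree v,
    as a function of v's own state (edge to the parent included)."""
    U: dict[int, np.ndarray] = {}
    first = D[id(tree.root)]
    U[id(tree.root)] = np.zeros_like(first)
    for node in tree.preorder():
        if node.is_leaf:
            continue
        mD = {id(c): _dt(D[id(c)]) for c in node.children}
        base = U[id(node)]
        for child in node.children:
            acc = base.copy()
            for other in node.children:
                if other is not child:
                    acc += mD[id(other)]
            U[id(child)] = _dt(acc)
    return U


def tree_length(
    tree: Tree,
    cm: CharacterMatrix,
    extra_rows: Optional[dict[str, np.ndarray]] = None,
) -> int:
    """Minimal total steps of all (ordered) characters on the topology."""
    rows = cm.state_dict()
    if extra_rows:
        rows.update(extra_rows)
    _leaf_rows(tree, rows)
    if _is_binary(tree):
        total, _ = _farris_length(tree, rows)
        return total
    D = _sankoff_down(tree, rows, cm.n_states)
    return int(D[id(tree.root)].min(axis=0).sum())


def char_length(
    tree: Tree,
    states: dict[str, int],
    ordered: bool = True,
    n_states: int = 24,
) -> int:
    """Minimal steps of a single character on a topology.

    ``ordered=True`` uses unit cost ``|i-j|`` (Wagner); ``ordered=False``
    uses Fitch-style unit cost for any state change (testing contrast only).
    """
    for leaf in tree.leaves():
        if leaf.taxon not in states:
            raise ValueError(f"leaf {leaf.taxon!r} has no state")
    if ordered:
        rows = {t: np.array([s], dtype=np.int16) for t, s in states.items()}
        D = _sankoff_down(tree, rows, n_states)
        return int(D[id(tree.root)].min())
    # unordered: Sankoff with 0/1 cost matrix
    S = n_states
    cost: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            vec = np.full(S, _INF, dtype=np.int32)
            vec[states[node.taxon]] = 0
            cost[id(node)] = vec
        else:
            acc = np.zeros(S, dtype=np.int32)
            for child in node.children:
                c = cost[id(child)]
                best = c.min()
                acc += np.minimum(c, best + 1)
            cost[id(node)] = acc
    return int(cost[id(tree.root)].min())


def _edge_insertion_lengths(
    tree: Tree,
    rows: dict[str, np.ndarray],
    x_row: np.ndarray,
    n_states: int,
) -> tuple[dict[int, int], int]:
    """Total tree length after inserting a leaf with states ``x_row`` on the
    edge above each non-root node; also returns the current length."""
    D = _sankoff_down(tree, rows, n_states)
    U = _sankoff_up(tree, D, n_states)
    xcost = _leaf_cost(x_row, n_states)
    current = int(D[id(tree.root)].min(axis=0).sum())
    out: dict[int, int] = {}
    for node in tree.postorder():
        if node.parent is None:
            continue
        mD = _dt(D[id(node)])
        total = (xcost + mD + U[id(node)]).min(axis=0).sum()
        out[id(node)] = int(total)
    return out, current


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------


def _greedy_addition(
    order: Sequence[str], rows: dict[str, np.ndarray], n_states: int
) -> Tree:
    root = Node()
    root.add(Node(order[0]))
    root.add(Node(order[1]))
    tree = Tree(root)
    for taxon in order[2:]:
        costs, _ = _edge_insertion_lengths(tree, rows, rows[taxon], n_states)
        nodes = [n for n in tree.postorder() if n.parent is not None]
        best = min(nodes, key=lambda n: costs[id(n)])
        tree.insert_leaf_above(best, taxon)
    return tree


def _score(tree: Tree, rows: dict[str, np.ndarray], n_states: int) -> int:
    if _is_binary(tree):
        return _farris_length(tree, rows)[0]
    D = _sankoff_down(tree, rows, n_states)
    return int(D[id(tree.root)].min(axis=0).sum())


def _nni_sweep(tree: Tree, rows: dict, n_states: int, length: int) -> tuple[Tree, int, bool]:
    """One first-improvement pass over all NNI rearrangements."""
    for v in list(tree.postorder()):
        u = v.parent
        if u is None or v.is_leaf:
            continue
        siblings = [w for w in u.children if w is not v]
        for w in siblings:
            for x in list(v.children):
                # swap subtree x (child of v) with sibling w of v
                iv = v.children.index(x)
                iu = u.children.index(w)
                v.children[iv], u.children[iu] = w, x
                w.parent, x.parent = v, u
                new_len = _score(tree, rows, n_states)
                if new_len < length:
                    return tree, new_len, True
                v.children[iv], u.children[iu] = x, w
                w.parent, x.parent = u, v
    return tree, length, False


def _regraft_targets(tree: Tree) -> list[Node]:
    return [n for n in tree.postorder() if n.parent is not None]


def _spr_sweep(tree: Tree, rows: dict, n_states: int, length: int) -> tuple[Tree, int, bool]:
    """One first-improvement pass over subtree-prune-regraft rearrangements."""
    n_nodes = len(tree.postorder())
    for p_idx in range(n_nodes):
        work = tree.copy()
        nodes = work.postorder()
        p = nodes[p_idx]
        if p.parent is None:
            continue
        sibling_is_all = p.parent.parent is None and all(
            c.is_leaf for c in p.parent.children if c is not p
        ) and len(p.parent.children) == 2
        if sibling_is_all:
            continue  # pruning would leave a single leaf
        sub = work.prune(p)
        for target in _regraft_targets(work):
            mid = Node()
            parent = target.parent
            idx = parent.children.index(target)
            parent.children[idx] = mid
            mid.parent = parent
            mid.add(target)
            mid.add(sub)
            new_len = _score(work, rows, n_states)
            if new_len < length:
                return work, new_len, True
            # undo
            mid.children.remove(sub)
            sub.parent = None
            parent.children[idx] = target
            target.parent = parent
            mid.children.clear()
    return tree, length, False


def _subtree_rerootings(sub: Tree) -> list[Tree]:
    """All rootings of a detached subtree along its edges (for TBR)."""
    if sub.root.is_leaf or len(sub.root.children) < 2:
        return [sub]
    out = []
    n_nodes = len(sub.postorder())
    for idx in range(n_nodes):
        work = sub.copy()
        node = work.postorder()[idx]
        if node.parent is None:
            continue
        work.reroot_above(node)
        out.append(work)
    seen: dict[str, Tree] = {}
    for t in out:
        seen.setdefault(t.canonical_newick(), t)
    return list(seen.values())


def _tbr_sweep(tree: Tree, rows: dict, n_states: int, length: int) -> tuple[Tree, int, bool]:
    n_nodes = len(tree.postorder())
    for p_idx in range(n_nodes):
        base = tree.copy()
        nodes = base.postorder()
        p = nodes[p_idx]
        if p.parent is None:
            continue
        if p.parent.parent is None and len(p.parent.children) == 2 and all(
            c.is_leaf for c in p.parent.children if c is not p
        ):
            continue
        sub = Tree(base.prune(p))
        for rerooted in _subtree_rerootings(sub):
            sub_root = rerooted.root
            for target in _regraft_targets(base):
                mid = Node()
                parent = target.parent
                idx = parent.children.index(target)
                parent.children[idx] = mid
                mid.parent = parent
                mid.add(target)
                mid.add(sub_root)
                new_len = _score(base, rows, n_states)
                if new_len < length:
                    return base, new_len, True
                mid.children.remove(sub_root)
                sub_root.parent = None
                parent.children[idx] = target
                target.parent = parent
                mid.children.clear()
    return tree, length, False


def _hill_climb(
    tree: Tree, rows: dict, n_states: int, swap: str, tbr_limit: int
) -> tuple[Tree, int]:
    length = _score(tree, rows, n_states)
    n_taxa = tree.n_leaves
    if swap == "TBR" and n_taxa > tbr_limit:
        sweeps = [_spr_sweep, _nni_sweep]
    elif swap == "TBR":
        sweeps = [_tbr_sweep]
    elif swap == "SPR":
        sweeps = [_spr_sweep]
    else:
        sweeps = [_nni_sweep]
    improved = True
    while improved:
        improved = False
        for sweep in sweeps:
            moved = True
            while moved:
                tree, length, moved = sweep(tree, rows, n_states, length)
                if moved:
                    improved = True
    return tree, length


def mp_search(cm: CharacterMatrix, cfg: Optional[SearchConfig] = None) -> list[Tree]:
    """Heuristic maximum-parsimony search.

    Random-addition starting trees followed by branch swapping; returns all
    distinct unrooted topologies achieving the best length found (up to
    ``cfg.maxtrees``), sorted by canonical form for determinism.
    """
    cfg = cfg or SearchConfig()
    if len(cm.taxa) < 3:
        raise ValueError("need at least 3 taxa for tree search")
    rows = cm.state_dict()
    rng = np.random.default_rng(cfg.seed)
    best_len = None
    best: dict[str, Tree] = {}
    for _ in range(cfg.n_addition_replicates):
        order = [cm.taxa[i] for i in rng.permutation(len(cm.taxa))]
        tree = _greedy_addition(order, rows, cm.n_states)
        tree, length = _hill_climb(tree, rows, cm.n_states, cfg.swap, cfg.tbr_taxon_limit)
        if best_len is None or length < best_len:
            best_len = length
            best = {tree.unrooted_key(): tree}
        elif length == best_len and len(best) < cfg.maxtrees:
            best.setdefault(tree.unrooted_key(), tree)
    return [best[k] for k in sorted(best)]


def exhaustive_search(cm: CharacterMatrix, max_taxa: int = 9) -> tuple[list[Tree], int]:
    """Global optimum by enumerating every unrooted binary topology."""
    taxa = cm.taxa
    if len(taxa) > max_taxa:
        raise ValueError(f"exhaustive search limited to {max_taxa} taxa")
    rows = cm.state_dict()
    best_len = None
    best: dict[str, Tree] = {}
    for tree in enumerate_topologies(taxa):
        length = _score(tree, rows, cm.n_states)
        if best_len is None or length < best_len:
            best_len = length
            best = {tree.unrooted_key(): tree}
        elif length == best_len:
            best.setdefault(tree.unrooted_key(), tree)
    return [best[k] for k in sorted(best)], int(best_len)


def enumerate_topologies(taxa: Sequence[str]) -> Iterable[Tree]:
    """Yield every unrooted binary topology on the given taxa (1,3,15,105...)."""

    def rec(tree: Tree, remaining: list[str]):
        if not remaining:
            yield tree.copy()
            return
        taxon = remaining[0]
        # the two root children mark the same unrooted edge: keep one
        skip = tree.root.children[1] if len(tree.root.children) == 2 else None
        nodes = [n for n in tree.postorder() if n.parent is not None and n is not skip]
        for node in nodes:
            leaf = tree.insert_leaf_above(node, taxon)
            yield from rec(tree, remaining[1:])
            mid = leaf.parent
            mid.children.remove(leaf)
            tree._suppress_unary(mid)

    root = Node()
    root.add(Node(taxa[0]))
    root.add(Node(taxa[1]))
    base = Tree(root)
    if len(taxa) == 2:
        yield base
        return
    yield from rec(base, list(taxa[2:]))


def random_topology(taxa: Sequence[str], rng: np.random.Generator) -> Tree:
    """A uniform random unrooted binary topology via random sequential addition."""
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    root = Node()
    root.add(Node(order[0]))
    root.add(Node(order[1]))
    tree = Tree(root)
    for taxon in order[2:]:
        skip = tree.root.children[1] if len(tree.root.children) == 2 else None
        nodes = [n for n in tree.postorder() if n.parent is not None and n is not skip]
        tree.insert_leaf_above(nodes[rng.integers(len(nodes))], taxon)
    return tree


# ---------------------------------------------------------------------------
# Lundberg rooting
# ---------------------------------------------------------------------------


def lundberg_root(tree: Tree, cm: CharacterMatrix) -> RootedTree:
    """Root an unrooted tree with a hypothetical all-ancestral-state taxon.

    The ancestor (all-0 for ``zero_ancestral`` polarity, all-max for
    ``max_ancestral``) is attached to the edge minimizing the total rooted
    length; ties are counted and broken deterministically (post-order).
    """
    rows = cm.state_dict()
    _leaf_rows(tree, rows)
    anc_state = cm.ancestor_state
    x_row = np.full(len(cm.characters), anc_state, dtype=np.int16)
    costs, unrooted = _edge_insertion_lengths(tree, rows, x_row, cm.n_states)
    # in the rooted representation the two root children mark the same
    # unrooted edge; keep only one so ties are counted per edge
    skip = tree.root.children[1] if len(tree.root.children) == 2 else None
    nodes = [n for n in tree.postorder() if n.parent is not None and n is not skip]
    node_costs = [costs[id(n)] for n in nodes]
    best = min(node_costs)
    ties = sum(1 for c in node_costs if c == best)
    target_idx = node_costs.index(best)
    # rebuild on a copy so the input tree is untouched
    work = tree.copy()
    work_nodes = [n for n in work.postorder() if n.parent is not None]
    target = work_nodes[target_idx]
    anc = Node(ANCESTOR_LABEL)
    mid = Node()
    parent = target.parent
    idx = parent.children.index(target)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add(target)
    mid.add(anc)
    work.reroot_above(anc)
    crown = next(c for c in work.root.children if c is not anc)
    return RootedTree(
        tree=work,
        crown=crown,
        length=int(best),
        unrooted_length=int(unrooted),
        ancestor_state=int(anc_state),
        n_states=cm.n_states,
        attachment_ties=ties,
    )


def rooted_rows(rt: RootedTree, cm: CharacterMatrix) -> dict[str, np.ndarray]:
    rows = cm.state_dict()
    rows[ANCESTOR_LABEL] = np.full(
        len(cm.characters), rt.ancestor_state, dtype=np.int16
    )
    return rows


# ---------------------------------------------------------------------------
# Tree statistics
# ---------------------------------------------------------------------------


def ci_ri(
    tree: Tree | RootedTree, cm: CharacterMatrix
) -> tuple[float, Optional[float]]:
    """Consistency and retention indices.

    CI = sum of per-character minima (max - min observed state, the ordered
    minimum) over the realized tree length; RI = (G - L) / (G - M) with G the
    'bush' length (best single ancestral state).  RI is None when G == M
    (no character could be retained: every character is invariant-like).
    For a Lundberg-rooted tree the hypothetical ancestor participates as a
    leaf, consistent with how the rooted length is computed.
    """
    if isinstance(tree, RootedTree):
        rows = rooted_rows(tree, cm)
        length = tree.length
        labels = tree.tree.leaf_labels()
    else:
        rows = cm.state_dict()
        length = tree_length(tree, cm)
        labels = tree.leaf_labels()
    mat = np.stack([rows[t] for t in labels])  # leaves x chars
    m = (mat.max(axis=0) - mat.min(axis=0)).astype(np.int64)
    med = np.median(mat, axis=0)
    g = np.abs(mat - np.floor(med)[None, :]).sum(axis=0)
    g2 = np.abs(mat - np.ceil(med)[None, :]).sum(axis=0)
    g = np.minimum(g, g2).astype(np.int64)
    M, G = int(m.sum()), int(g.sum())
    ci = 1.0 if length == 0 else M / length
    ri = None if G == M else (G - length) / (G - M)
    return ci, ri


def g1_skewness(
    cm: CharacterMatrix, n_random: int = 1000, seed: Optional[int] = None
) -> float:
    """Fisher-Pearson skewness of the random-tree length distribution.

    Strongly left-skewed distributions (g1 < 0) indicate phylogenetic
    signal: few trees are much shorter than the bulk.
    """
    if len(cm.taxa) < 4:
        raise ValueError("g1 needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    rows = cm.state_dict()
    lengths = np.empty(n_random)
    for i in range(n_random):
        tree = random_topology(cm.taxa, rng)
        lengths[i] = _score(tree, rows, cm.n_states)
    if np.ptp(lengths) == 0:
        return 0.0
    return float(stats.skew(lengths, bias=True))


# ---------------------------------------------------------------------------
# Bootstrap and consensus
# ---------------------------------------------------------------------------


def _splits(tree: Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions, each written as the side not containing the
    alphabetically first taxon."""
    all_taxa = frozenset(tree.leaf_labels())
    ref = min(all_taxa)
    out: set[frozenset[str]] = set()
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.taxon])
        else:
            side = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = side
            if node.parent is not None:
                if ref in side:
                    side = all_taxa - side
                if 1 < len(side) < len(all_taxa) - 1:
                    out.add(side)
    return out


def bootstrap(
    cm: CharacterMatrix,
    reps: int = 100,
    cfg: Optional[SearchConfig] = None,
    ref_tree: Optional[Tree] = None,
) -> tuple[Tree, dict[frozenset[str], float]]:
    """Nonparametric bootstrap support for the clades of a reference tree.

    Characters are resampled with replacement to the original count; each
    replicate is searched with ``cfg`` and the first best tree's bipartitions
    are tallied.  Returns the reference tree and percent support per clade.
    """
    cfg = cfg or SearchConfig()
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    if ref_tree is None:
        ref_tree = mp_search(cm, cfg)[0]
    ref_splits = _splits(ref_tree)
    tally = {s: 0 for s in ref_splits}
    n_chars = len(cm.characters)
    for rep in range(reps):
        idx = rng.integers(0, n_chars, size=n_chars)
        boot = CharacterMatrix(
            taxa=list(cm.taxa),
            characters=[f"{cm.characters[i]}@{j}" for j, i in enumerate(idx)],
            states=cm.states[:, idx].copy(),
            polarity=cm.polarity,
            n_states=cm.n_states,
        )
        sub_cfg = SearchConfig(
            n_addition_replicates=1,
            swap=cfg.swap,
            maxtrees=1,
            seed=int(rng.integers(2**31 - 1)),
            tbr_taxon_limit=cfg.tbr_taxon_limit,
        )
        rep_tree = mp_search(boot, sub_cfg)[0]
        rep_splits = _splits(rep_tree)
        for s in ref_splits:
            if s in rep_splits:
                tally[s] += 1
    return ref_tree, {s: 100.0 * n / reps for s, n in tally.items()}


def consensus_majority(trees: Sequence[Tree], cutoff: float = 0.5) -> Tree:
    """Majority-rule consensus (clades above ``cutoff`` frequency) via
    dendropy (the SumTrees engine)."""
    if not trees:
        raise ValueError("need at least one tree")
    if len(trees) == 1:
        return trees[0].copy()
    tns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(
        [
            dendropy.Tree.get(
                data=t.newick(), schema="newick", taxon_namespace=tns,
                suppress_internal_node_taxa=True,
            )
            for t in trees
        ]
    )
    # strict majority: a clade must occur in MORE than cutoff of the trees
    con = tl.consensus(min_freq=min(cutoff + 1e-9, 1.0))
    newick = con.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=True,
        unquoted_underscores=True,
    )
    return Tree.from_newick(newick.strip())
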