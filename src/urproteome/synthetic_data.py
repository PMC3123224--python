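"""Synthetic proteome x FSF abundance censuses with known ground truth.

The generator emulates the evolutionary model behind abundance-based
phylogenomics: domain repertoires grow progressively, so ancient
superfamilies are more abundant and more widely shared than young ones.
Concretely, a guide tree of proteomes with three superkingdom clades
(Archaea basal: ((B, E), A)) is walked root-to-tips; each fold superfamily
is born on some branch — ancestral FSFs at the root with several seed
copies, derived FSFs on internal branches inside a single superkingdom
clade with one copy — and every copy duplicates with a per-FSF probability
per branch step (geometric growth with depth; derived FSFs draw
heterogeneous expansion rates, giving the heavy-tailed abundance spread of
real censuses).  Lineage losses drop an FSF from individual leaf lineages
with a small probability, and optional horizontal transfer copies an FSF's
presence and abundance from a donor lineage into a foreign subtree.

Every stochastic choice flows from one seed, so fixtures are reproducible
bit for bit and every downstream inference can be scored against the
implanted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._tree import Node, Tree
from .census_io import AbundanceMatrix
from .function_enrichment import CATEGORIES, FunctionMap

SK_PREFIX = {"A": "A", "B": "B", "E": "E"}


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults describe the paper-like fixture: 10 free-living proteomes per
    superkingdom, 300 FSFs of which 40 are implanted at the root, a 2%
    chance per leaf lineage of losing any given FSF, and no horizontal
    transfer unless asked for.

    Abundance dynamics mirror real censuses, where ancient housekeeping
    superfamilies are abundant but comparatively stable across lineages
    while young signature superfamilies expand in lineage-specific bursts:
    ancestral FSFs start with ``ancestral_seed_copies`` copies at the root
    (the urancestral repertoire is modeled as already redundant) and
    duplicate at ``ancestral_duplication_rate`` per copy per branch step,
    keeping them at the top of the abundance spectrum as in real censuses;
    each derived FSF is born with one copy and draws its own expansion rate
    uniformly between ``duplication_rate`` and ``expansion_rate_max``,
    producing large abundance variance without letting young superfamilies
    overtake the ancient tier.
    """

    n_proteomes_per_sk: int = 10
    n_ancestral_fsfs: int = 40
    n_derived_fsfs: int = 260
    duplication_rate: float = 0.1
    expansion_rate_max: float = 0.5
    ancestral_duplication_rate: float = 0.3
    loss_prob: float = 0.02
    hgt_rate: float = 0.0
    tree_shape: str = "random"  # ladder | balanced | random
    ancestral_seed_copies: int = 8
    clade_birth_weights: tuple[float, float, float] = (1.0, 2.0, 3.0)  # A, B, E
    birth_basal_bias: float = 0.0  # chance a derived FSF is born at its clade base
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteomes_per_sk < 1:
            raise ValueError("need at least one proteome per superkingdom")
        for name in ("duplication_rate", "loss_prob", "hgt_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.expansion_rate_max < self.duplication_rate:
            raise ValueError("expansion_rate_max must be >= duplication_rate")
        if not (self.loss_prob <= 1 and self.hgt_rate <= 1):
            raise ValueError("probabilities must be <= 1")
        if self.tree_shape not in ("ladder", "balanced", "random"):
            raise ValueError(f"unknown tree shape {self.tree_shape!r}")


@dataclass
class GroundTruth:
    """What the generator implanted, for scoring inferences."""

    guide_tree: Tree
    birth_node: dict[str, str]  # fsf -> internal-node label
    ancestral_set: set[str]
    loss_events: list[tuple[str, str]] = field(default_factory=list)  # (fsf, node)
    hgt_events: list[tuple[str, str, str]] = field(default_factory=list)  # (fsf, donor, node)
    extinct: set[str] = field(default_factory=set)


def _clade(leaves: list[str], shape: str, rng: np.random.Generator) -> Node:
    if len(leaves) == 1:
        return Node(leaves[0])
    if shape == "ladder":
        node = Node(leaves[-1])
        for taxon in reversed(leaves[:-1]):
            top = Node()
            top.add(Node(taxon))
            top.add(node)
            node = top
        return node
    if shape == "balanced":
        mid = len(leaves) // 2
        node = Node()
        node.add(_clade(leaves[:mid], shape, rng))
        node.add(_clade(leaves[mid:], shape, rng))
        return node
    # random: sequential addition to a uniformly chosen edge
    root = Node()
    root.add(Node(leaves[0]))
    root.add(Node(leaves[1]))
    tree = Tree(root)
    for taxon in leaves[2:]:
        nodes = [n for n in tree.postorder() if n.parent is not None]
        tree.insert_leaf_above(nodes[rng.integers(len(nodes))], taxon)
    return tree.root


def build_guide_tree(cfg: SimConfig, rng: np.random.Generator) -> Tree:
    """Rooted guide tree ((B, E), A): Archaea basal, per-clade shape."""
    width = len(str(cfg.n_proteomes_per_sk))
    names = {
        sk: [f"{sk}{i + 1:0{width}d}" for i in range(cfg.n_proteomes_per_sk)]
        for sk in ("A", "B", "E")
    }
    root = Node()
    inner = Node()
    inner.add(_clade(names["B"], cfg.tree_shape, rng))
    inner.add(_clade(names["E"], cfg.tree_shape, rng))
    root.add(inner)
    root.add(_clade(names["A"], cfg.tree_shape, rng))
    tree = Tree(root)
    for i, node in enumerate(tree.preorder()):
        if not node.is_leaf:
            node.taxon = None
        # internal nodes get stable labels via a side table; see _node_labels
    return tree


def _node_labels(tree: Tree) -> dict[int, str]:
    labels = {}
    for i, node in enumerate(tree.preorder()):
        labels[id(node)] = node.taxon if node.is_leaf else f"n{i}"
    return labels


def _superkingdom_subtrees(tree: Tree) -> dict[str, Node]:
    """Root node of each superkingdom clade, identified by leaf prefixes."""
    out = {}
    below: dict[int, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.taxon[0]}
        else:
            below[id(node)] = set().union(*(below[id(c)] for c in node.children))
    for sk in ("A", "B", "E"):
        candidates = [
            n
            for n in tree.postorder()
            if below[id(n)] == {sk}
            and (n.parent is None or below[id(n.parent)] != {sk})
        ]
        out[sk] = candidates[0]
    return out


def simulate(cfg: SimConfig) -> tuple[AbundanceMatrix, GroundTruth]:
    """Generate an abundance census and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    tree = build_guide_tree(cfg, rng)
    labels = _node_labels(tree)
    leaves = tree.leaves()
    internal = [n for n in tree.postorder() if not n.is_leaf]
    sk_roots = _superkingdom_subtrees(tree)

    anc_fsfs = [f"a.{i + 1}.1" for i in range(cfg.n_ancestral_fsfs)]
    der_fsfs = [f"d.{i + 1}.1" for i in range(cfg.n_derived_fsfs)]
    truth = GroundTruth(
        guide_tree=tree,
        birth_node={},
        ancestral_set=set(anc_fsfs),
    )

    births: dict[int, list[str]] = {id(tree.root): list(anc_fsfs)}
    for f in anc_fsfs:
        truth.birth_node[f] = labels[id(tree.root)]
    # derived births are clade-weighted: eukaryal lineages accumulate the
    # most signature FSFs and archaeal lineages the fewest, mirroring the
    # observed asymmetry of superkingdom signatures
    sks = ["A", "B", "E"]
    weights = np.asarray(cfg.clade_birth_weights, dtype=float)
    weights = weights / weights.sum()
    rate: dict[str, float] = {f: cfg.ancestral_duplication_rate for f in anc_fsfs}
    for f in der_fsfs:
        clade_root = sk_roots[sks[rng.choice(3, p=weights)]]
        pool = [n for n in Tree(clade_root).postorder() if not n.is_leaf] or [clade_root]
        # signature FSFs are mostly clade-wide: with probability
        # birth_basal_bias the FSF arises at the base of its superkingdom
        if rng.random() < cfg.birth_basal_bias:
            node = clade_root
        else:
            node = pool[rng.integers(len(pool))]
        births.setdefault(id(node), []).append(f)
        truth.birth_node[f] = labels[id(node)]
        rate[f] = float(rng.uniform(cfg.duplication_rate, cfg.expansion_rate_max))

    # main preorder pass: inherit counts, duplicate, then add births
    counts: dict[int, dict[str, int]] = {}
    for node in tree.preorder():
        if node.parent is None:
            here: dict[str, int] = {}
        else:
            here = {
                f: c + int(rng.binomial(c, rate[f]))
                for f, c in counts[id(node.parent)].items()
            }
        for f in births.get(id(node), []):
            here[f] = cfg.ancestral_seed_copies if f in truth.ancestral_set else 1
        counts[id(node)] = here

    # HGT pass: per derived FSF, with probability hgt_rate, copy its presence
    # and abundance from a donor lineage into a foreign internal node and let
    # it keep duplicating down that subtree
    if cfg.hgt_rate > 0:
        for f in der_fsfs:
            if rng.random() >= cfg.hgt_rate:
                continue
            native = {id(n) for n in _subtree_nodes_of(tree, truth.birth_node[f], labels)}
            donors = [n for n in leaves if id(n) in native and counts[id(n)].get(f, 0) > 0]
            options = [n for n in internal if id(n) not in native and n.parent is not None]
            if not donors or not options:
                continue
            donor = donors[rng.integers(len(donors))]
            recipient = options[rng.integers(len(options))]
            truth.hgt_events.append((f, donor.taxon, labels[id(recipient)]))
            stack = [(recipient, counts[id(donor)][f])]
            while stack:
                node, c = stack.pop()
                counts[id(node)][f] = counts[id(node)].get(f, 0) + c
                for child in node.children:
                    stack.append((child, c + int(rng.binomial(c, rate[f]))))

    # lineage losses: each (FSF, leaf) pair independently drops out
    for leaf in leaves:
        here = counts[id(leaf)]
        for f in sorted(here):
            if here[f] > 0 and rng.random() < cfg.loss_prob:
                here[f] = 0
                truth.loss_events.append((f, leaf.taxon))

    proteomes = [n.taxon for n in leaves]
    fsfs = anc_fsfs + der_fsfs
    g = pd.DataFrame(0, index=fsfs, columns=proteomes, dtype=np.int64)
    for leaf in leaves:
        for f, c in counts[id(leaf)].items():
            g.loc[f, leaf.taxon] = c
    extinct = g.sum(axis=1) == 0
    truth.extinct = set(g.index[extinct])
    g = g.loc[~extinct]
    meta = pd.DataFrame(
        {
            "proteome_id": proteomes,
            "superkingdom": [p[0] for p in proteomes],
            "lifestyle": ["FL"] * len(proteomes),
        }
    ).set_index("proteome_id")
    return AbundanceMatrix(g=g, meta=meta), truth


def _subtree_nodes_of(tree: Tree, label: str, labels: dict[int, str]) -> list[Node]:
    start = next(n for n in tree.preorder() if labels[id(n)] == label)
    out = []
    stack = [start]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

FIXTURES = {
    "tiny": SimConfig(
        n_proteomes_per_sk=3,
        n_ancestral_fsfs=8,
        n_derived_fsfs=16,
        duplication_rate=0.1,
        expansion_rate_max=0.4,
        loss_prob=0.0,
        hgt_rate=0.0,
        tree_shape="ladder",
        seed=7,
    ),
    "paper_like": SimConfig(
        n_proteomes_per_sk=10,
        n_ancestral_fsfs=40,
        n_derived_fsfs=260,
        duplication_rate=0.1,
        expansion_rate_max=0.5,
        loss_prob=0.02,
        hgt_rate=0.02,
        tree_shape="random",
        seed=2011,
    ),
}


def make_fixture(name: str) -> tuple[AbundanceMatrix, GroundTruth, SimConfig]:
    """Bundled datasets: ``tiny`` (9 proteomes x 24 FSFs, hand-checkable) and
    ``paper_like`` (30 proteomes x 300 FSFs, 40 implanted ancestral FSFs,
    lineage loss and light horizontal transfer)."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; have {sorted(FIXTURES)}")
    cfg = FIXTURES[name]
    m, truth = simulate(cfg)
    return m, truth, cfg


def toy_function_map(fsfs: list[str], seed: int = 0) -> FunctionMap:
    """A small synthetic function map spreading FSFs over sub-categories."""
    rng = np.random.default_rng(seed)
    subs = {
        "General": ["small molecule binding", "protein interaction"],
        "Information": ["translation", "DNA replication/repair"],
        "Metabolism": ["transferases", "nucleotide m/tr", "redox"],
        "Intra-cellular processes": ["transport", "proteases"],
        "Regulation": ["DNA-binding", "kinases/phosphatases"],
        "Other": ["unknown function"],
    }
    flat = [(cat, sub) for cat, ss in subs.items() for sub in ss]
    mapping = {}
    for f in fsfs:
        cat, sub = flat[rng.integers(len(flat))]
        mapping[f] = (cat, sub)
    return FunctionMap.from_dict(mapping)


# ---------------------------------------------------------------------------
# Export as census files (round-trip through census_io)
# ---------------------------------------------------------------------------


def write_assignments(m: AbundanceMatrix, path: str | Path, evalue: float = 1e-10) -> None:
    """Expand the matrix into a SUPERFAMILY-style assignment TSV."""
    with open(path, "w") as fh:
        fh.write("proteome_id\tprotein_id\tccs\tevalue\n")
        for p in m.proteomes:
            k = 0
            for f in m.fsfs:
                for _ in range(int(m.g.loc[f, p])):
                    fh.write(f"{p}\t{p}_prot{k}\t{f}.1\t{evalue:g}\n")
                    k += 1


def write_meta(m: AbundanceMatrix, path: str | Path) -> None:
    m.meta.to_csv(path, sep="\t", index_label="proteome_id")


def write_calibrations(
    path: str | Path,
    points: list[tuple[str, float, float]],
) -> None:
    """Calibration TSV: fsf_id, nd, age_Ga."""
    pd.DataFrame(points, columns=["fsf_id", "nd", "age_Ga"]).to_csv(
        path, sep="\t", index=False
    )
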