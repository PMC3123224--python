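"""Node-distance timelines and the linear molecular clock of domain ages.

Because the trees are rooted and highly unbalanced, the relative age of a
taxon is measured as its node distance (nd): the number of internal nodes
along its lineage from the root, normalized by the deepest lineage so that
nd spans [0, 1].  The most ancestral taxon has nd = 0; the most recent, 1.
Counting excludes the root-adjacent node itself, so a taxon branching
directly off the root is maximally ancestral.

A linear clock maps nd to geological age (Ga before present) by ordinary
least squares on calibration points (FSFs whose nd can be tied to dated
events); the fitted line is inverted to date uncalibrated taxa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import numpy as np
from scipy import stats

from ._tree import Tree
from .parsimony_engine import ANCESTOR_LABEL, RootedTree


@dataclass
class ClockModel:
    """nd = slope * age + intercept, fitted by OLS (nd is the response)."""

    slope: float
    intercept: float
    r2: float

    def nd_at(self, age_ga: float) -> float:
        return self.slope * age_ga + self.intercept

    def age_at(self, nd: float) -> float:
        if self.slope == 0:
            raise ValueError("degenerate clock: zero slope")
        return (nd - self.intercept) / self.slope


def compute_nd(tree: RootedTree | Tree) -> dict[str, float]:
    """Node-distance (relative age) per taxon of a rooted tree.

    The count is the number of internal nodes strictly between the crown
    (root-adjacent) node and the leaf, normalized by its maximum m.  On a
    degenerate tree with m = 0 (two leaves) all nd are 0, with a warning.
    """
    if isinstance(tree, RootedTree):
        start = tree.crown
        skip = {ANCESTOR_LABEL}
    else:
        start = tree.root
        skip = set()
    depths: dict[str, int] = {}

    def walk(node, internal_seen: int) -> None:
        if node.is_leaf:
            if node.taxon not in skip:
                depths[node.taxon] = internal_seen
            return
        for child in node.children:
            walk(child, internal_seen + (0 if node is start else 1))

    walk(start, 0)
    if not depths:
        raise ValueError("rooted tree has no scoreable leaves")
    m = max(depths.values())
    if m == 0:
        warnings.warn("degenerate tree: all leaves attach at the root; nd set to 0")
        return {t: 0.0 for t in depths}
    return {t: d / m for t, d in depths.items()}


def fit_clock(calibrations: Sequence[tuple[float, float]]) -> ClockModel:
    """OLS fit of nd on age from (age_Ga, nd) calibration pairs."""
    if len(calibrations) < 2:
        raise ValueError("need at least 2 calibration points")
    ages = np.array([a for a, _ in calibrations], dtype=float)
    nds = np.array([n for _, n in calibrations], dtype=float)
    if np.ptp(ages) == 0:
        raise ValueError("calibration ages are all identical")
    res = stats.linregress(ages, nds)
    return ClockModel(slope=float(res.slope), intercept=float(res.intercept),
                      r2=float(res.rvalue**2))


def nd_to_age(nd: float | Iterable[float], model: ClockModel):
    """Invert the clock: geological age (Ga) for one or many nd values."""
    if np.isscalar(nd):
        return model.age_at(float(nd))
    return np.array([model.age_at(float(x)) for x in nd])
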