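"""Shared fixtures: small hand-built matrices and one cached paper-like run.

The paper-like end-to-end objects (census, proteome tree, refinement,
structure-tree timeline) are expensive, so they are computed once per
session and shared by the recovery and synthetic-data tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import urproteome as up
from urproteome.ancestral_reconstruction import plesiomorphic_set, root_branch_changes
from urproteome.character_coding import CharacterMatrix, recode, transpose_for_structure_tree
from urproteome.parsimony_engine import SearchConfig, lundberg_root, mp_search
from urproteome.synthetic_data import make_fixture


@pytest.fixture
def quartet_matrix() -> CharacterMatrix:
    """Four taxa, one perfectly compatible ordered character {0,0,3,3}."""
    return CharacterMatrix(
        ["a", "b", "c", "d"], ["c0"], np.array([[0], [0], [3], [3]]), n_states=24
    )


@pytest.fixture
def random_matrix_factory():
    def make(n_taxa: int, n_chars: int, max_state: int = 5, seed: int = 0) -> CharacterMatrix:
        rng = np.random.default_rng(seed)
        return CharacterMatrix(
            [f"t{i}" for i in range(n_taxa)],
            [f"c{j}" for j in range(n_chars)],
            rng.integers(0, max_state, size=(n_taxa, n_chars)).astype(np.int16),
            n_states=24,
        )

    return make


@dataclass
class PaperLikeRun:
    matrix: "up.AbundanceMatrix"
    truth: "up.GroundTruth"
    cm: CharacterMatrix
    ancestral: set[str]
    rooted: "up.RootedTree"
    root_set: "up.PlesiomorphicSet"
    refinement: "up.RefinementResult"
    max_set: set[str]
    structure_nd: dict[str, float]
    occurrence: dict[str, str]
    basal: set[str]
    min_set: set[str]


@pytest.fixture(scope="session")
def paper_like_run() -> PaperLikeRun:
    """One full inference pass over the bundled paper-like fixture."""
    m, truth, _cfg = make_fixture("paper_like")
    cm = recode(m)
    ancestral = truth.ancestral_set & set(cm.characters)
    trees = mp_search(cm, SearchConfig(n_addition_replicates=2, swap="NNI", seed=1))
    rooted = lundberg_root(trees[0], cm)
    root_set = plesiomorphic_set(root_branch_changes(rooted, cm))
    refinement = up.run_refinement(cm, root_set.members, n_chains=3, n_iter=10, seed=42)
    st = transpose_for_structure_tree(cm)
    st_trees = mp_search(st, SearchConfig(n_addition_replicates=1, swap="NNI", seed=5))
    structure_nd = up.compute_nd(lundberg_root(st_trees[0], st))
    occurrence = up.classify_occurrence(m)
    basal = up.basal_set(structure_nd, occurrence)
    return PaperLikeRun(
        matrix=m,
        truth=truth,
        cm=cm,
        ancestral=ancestral,
        rooted=rooted,
        root_set=root_set,
        refinement=refinement,
        max_set=refinement.max_set,
        structure_nd=structure_nd,
        occurrence=occurrence,
        basal=basal,
        min_set=refinement.max_set & basal,
    )
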