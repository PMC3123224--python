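"""Superkingdom occurrence classes, popularity indices, and urancestral sets.

Each FSF is classified by presence (g > 0) across the three superkingdoms
(A, B, E and their unions, seven classes in total).  Two popularity indices
summarize how widespread and how reused an FSF is:

* ``f`` — the fraction of proteomes containing the FSF (0-1);
* ``meanG`` — total abundance summed over proteomes divided by the number of
  proteomes.

The *basal set* is read off the timeline of the tree of domain structures:
all FSFs that appear strictly before the first FSF not shared by all three
superkingdoms (ties at that boundary nd excluded — conservative, since the
set serves as a lower bound).  Intersecting it with the iteratively refined
maximal root set yields the minimal urancestral repertoire.  Urancestral
repertoires can also be re-injected as artificial taxa with maximal coded
abundance for member FSFs and zero elsewhere, to check that they resolve at
the base of trees of proteomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional
import warnings

import numpy as np
import pandas as pd

from .census_io import SUPERKINGDOMS, AbundanceMatrix, CensusError
from .character_coding import CharacterMatrix


@dataclass
class UrancestralSets:
    """Nested upper/lower bounds of the urancestral FSF repertoire."""

    root_set: set[str]
    max_set: set[str]
    basal_set: set[str]
    min_set: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.min_set = self.max_set & self.basal_set


def classify_occurrence(m: AbundanceMatrix) -> dict[str, str]:
    """Seven-way superkingdom occurrence label (A/B/E/AB/AE/BE/ABE) per FSF."""
    sk = m.meta["superkingdom"]
    groups = {s: [p for p in m.proteomes if sk[p] == s] for s in SUPERKINGDOMS}
    empty = [s for s, ps in groups.items() if not ps]
    if empty:
        raise CensusError(f"superkingdoms without proteomes: {empty}")
    out: dict[str, str] = {}
    for fsf in m.fsfs:
        row = m.g.loc[fsf]
        label = "".join(s for s in SUPERKINGDOMS if (row[groups[s]] > 0).any())
        out[fsf] = label
    return out


def popularity(m: AbundanceMatrix) -> pd.DataFrame:
    """Distribution index f and mean abundance (meanG) per FSF."""
    if m.g.size == 0:
        raise CensusError("empty abundance matrix")
    n = len(m.proteomes)
    f = (m.g > 0).sum(axis=1) / n
    mean_g = m.g.sum(axis=1) / n
    return pd.DataFrame({"f": f, "meanG": mean_g})


def basal_set(
    fsf_nd: Mapping[str, float], occurrence: Mapping[str, str]
) -> set[str]:
    """FSFs older than the first non-universal FSF on the structure-tree
    timeline.

    All FSFs with nd strictly below the minimum nd of FSFs whose occurrence
    label is not ABE; FSFs tied at that boundary nd are excluded.  If every
    FSF is universal the whole set is returned, with a warning.
    """
    non_abe = [nd for f, nd in fsf_nd.items() if occurrence.get(f, "ABE") != "ABE"]
    if not non_abe:
        warnings.warn("no non-universal FSF in the timeline; basal set is everything")
        return set(fsf_nd)
    boundary = min(non_abe)
    return {f for f, nd in fsf_nd.items() if nd < boundary}


def inject_urancestor(
    cm: CharacterMatrix, ur_set: set[str], label: str
) -> CharacterMatrix:
    """Append an artificial urancestral taxon to a proteome character matrix.

    Member FSFs get the maximal character state (maximal transformed
    abundance); all others get 0.
    """
    if label in cm.taxa:
        raise ValueError(f"duplicate taxon label {label!r}")
    unknown = set(ur_set) - set(cm.characters)
    if unknown:
        raise ValueError(f"urancestral FSFs not in the matrix: {sorted(unknown)[:5]}")
    row = np.zeros((1, len(cm.characters)), dtype=np.int16)
    for j, char in enumerate(cm.characters):
        if char in ur_set:
            row[0, j] = cm.n_states - 1
    return CharacterMatrix(
        taxa=list(cm.taxa) + [label],
        characters=list(cm.characters),
        states=np.vstack([cm.states, row]),
        polarity=cm.polarity,
        n_states=cm.n_states,
    )


def occurrence_summary(occurrence: Mapping[str, str]) -> pd.Series:
    """Venn-cell counts over the seven occurrence classes."""
    order = ["A", "B", "E", "AB", "AE", "BE", "ABE"]
    counts = pd.Series(0, index=order, dtype=int)
    for label in occurrence.values():
        counts[label] += 1
    return counts
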