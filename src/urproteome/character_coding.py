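"""Recoding of raw genomic abundances into ordered parsimony characters.

Raw abundance counts ``g`` span zero to hundreds.  For parsimony analysis they
are compressed onto a small linearly ordered scale (24 states by default,
written ``0``-``9`` then ``A``-``N``, a PAUP*-compatible alphanumeric
encoding).  The default transform normalizes each count by the matrix-wide
maximum and rounds:

    state = round( g_ab / g_max * (n_states - 1) )

with half-away-from-zero rounding.  A logarithmic variant
``ln(g+1)/ln(g_max+1)`` compresses the heavy upper tail of abundance
distributions, and normalization can optionally be per character instead of
matrix-wide.  Character polarity declares which extreme is ancestral:
``zero_ancestral`` for trees of proteomes (repertoires grow from nothing) and
``max_ancestral`` for trees of domain structures (ancient superfamilies are
the most abundant and widespread).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .census_io import AbundanceMatrix

SYMBOLS = "0123456789ABCDEFGHIJKLMN"

ZERO_ANCESTRAL = "zero_ancestral"
MAX_ANCESTRAL = "max_ancestral"


@dataclass
class CharacterMatrix:
    """Ordered multistate character matrix (taxa x characters).

    ``states`` holds integers in ``[0, n_states)``; ``polarity`` declares the
    hypothetical-ancestor state used for Lundberg rooting (all-0 or all-max).
    """

    taxa: list[str]
    characters: list[str]
    states: np.ndarray
    polarity: str = ZERO_ANCESTRAL
    n_states: int = 24

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.shape != (len(self.taxa), len(self.characters)):
            raise ValueError(
                f"state array shape {self.states.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        if self.states.size and (self.states.min() < 0 or self.states.max() >= self.n_states):
            raise ValueError("states outside the declared 0..n_states-1 range")
        if self.polarity not in (ZERO_ANCESTRAL, MAX_ANCESTRAL):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.n_states < 2 or self.n_states > len(SYMBOLS):
            raise ValueError(f"n_states must be in [2, {len(SYMBOLS)}]")

    # -- encoding ---------------------------------------------------------

    @property
    def symbols(self) -> str:
        return SYMBOLS[: self.n_states]

    @property
    def ancestor_state(self) -> int:
        return 0 if self.polarity == ZERO_ANCESTRAL else self.n_states - 1

    def encode_row(self, i: int) -> str:
        return "".join(self.symbols[s] for s in self.states[i])

    @staticmethod
    def decode_symbols(text: str, n_states: int = 24) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(SYMBOLS[:n_states])}
        try:
            return np.array([lookup[c] for c in text], dtype=np.int16)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"symbol {exc} outside the 0-{n_states - 1} state alphabet")

    # -- convenience ------------------------------------------------------

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {t: self.states[i] for i, t in enumerate(self.taxa)}

    def restrict(self, characters: list[str] | set[str]) -> "CharacterMatrix":
        """Keep only the given characters (order follows the current matrix)."""
        keep = [i for i, c in enumerate(self.characters) if c in set(characters)]
        return replace(
            self,
            characters=[self.characters[i] for i in keep],
            states=self.states[:, keep].copy(),
        )

    def drop_taxon(self, taxon: str) -> "CharacterMatrix":
        keep = [i for i, t in enumerate(self.taxa) if t != taxon]
        return replace(self, taxa=[self.taxa[i] for i in keep], states=self.states[keep].copy())

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round uses banker's rounding; the coding contract fixes ties away
    # from zero so matrices never silently depend on float parity behavior.
    return np.floor(x + 0.5)


def recode(
    m: "AbundanceMatrix",
    n_states: int = 24,
    scale: str = "linear",
    per_character: bool = False,
) -> CharacterMatrix:
    """Transform an abundance matrix into ordered character states.

    Parameters
    ----------
    m:
        Abundance matrix (FSFs x proteomes).
    n_states:
        Number of ordered states (24 gives the ``0``-``N`` alphabet).
    scale:
        ``"linear"``: ``round(g/g_max * (n_states-1))``;
        ``"log"``: ``round(ln(g+1)/ln(g_max+1) * (n_states-1))``.
    per_character:
        Normalize by each character's own maximum instead of the matrix-wide
        maximum (sensitivity-analysis option).

    Returns a proteome-rows matrix (taxa = proteomes, characters = FSFs) with
    ``zero_ancestral`` polarity; transpose with
    :func:`transpose_for_structure_tree` for trees of domain structures.
    """
    if scale not in ("linear", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    g = m.g.to_numpy(dtype=float)  # fsfs x proteomes
    if g.size == 0:
        raise ValueError("cannot recode an empty abundance matrix")
    if per_character:
        gmax = g.max(axis=1, keepdims=True)
        gmax[gmax == 0] = 1.0
    else:
        gmax = g.max()
        if gmax <= 0:
            raise ValueError("matrix maximum abundance must be positive")
    if scale == "linear":
        frac = g / gmax
    else:
        frac = np.log(g + 1.0) / np.log(np.asarray(gmax, dtype=float) + 1.0)
    states = _round_half_away(frac * (n_states - 1)).astype(np.int16)
    return CharacterMatrix(
        taxa=list(m.proteomes),
        characters=list(m.fsfs),
        states=states.T,
        polarity=ZERO_ANCESTRAL,
        n_states=n_states,
    )


def transpose_for_structure_tree(cm: CharacterMatrix) -> CharacterMatrix:
    """Swap taxa and characters to build trees of domain structures.

    In the transposed matrix the taxa are FSFs and the characters are
    proteomes; polarity flips to ``max_ancestral`` because the most ancient
    structures are assumed to be the most abundant ('N' ancestral).
    """
    return CharacterMatrix(
        taxa=list(cm.characters),
        characters=list(cm.taxa),
        states=cm.states.T.copy(),
        polarity=MAX_ANCESTRAL if cm.polarity == ZERO_ANCESTRAL else ZERO_ANCESTRAL,
        n_states=cm.n_states,
    )
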