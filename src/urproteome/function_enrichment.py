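"""Coarse-grained molecular functions of FSFs and enrichment testing.

FSFs are annotated with one of 49 functional sub-categories nested in seven
major categories (the Vogel-Chothia coarse-grained scheme: General,
Information, Metabolism, Intra-cellular processes, Extra-cellular processes,
Regulation, Other); unannotated FSFs are excluded from testing.  Enrichment
of a sub-category in a sample of FSFs relative to a background is assessed
with the exact hypergeometric upper tail P(X >= k): drawing n FSFs from a
universe of N, of which M carry the sub-category, what is the chance of
seeing k or more?  Only sub-categories whose sample rate exceeds the
background rate are tested; no multiple-testing correction is applied by
default (a Benjamini-Hochberg option is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .census_io import AbundanceMatrix
from .character_coding import CharacterMatrix, recode

NOT_ANNOTATED = "not annotated"

CATEGORIES = (
    "General",
    "Information",
    "Metabolism",
    "Intra-cellular processes",
    "Extra-cellular processes",
    "Regulation",
    "Other",
)


@dataclass
class FunctionMap:
    """FSF -> (major category, sub-category) assignment."""

    table: pd.DataFrame  # index: fsf_id; columns: category, subcategory

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FunctionMap":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        df.columns = [c.lower() for c in df.columns]
        df = df[["fsf_id", "category", "subcategory"]].set_index("fsf_id")
        return cls(df)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, tuple[str, str]]) -> "FunctionMap":
        df = pd.DataFrame(
            [(f, c, s) for f, (c, s) in mapping.items()],
            columns=["fsf_id", "category", "subcategory"],
        ).set_index("fsf_id")
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="fsf_id")

    def subcategory(self, fsf: str) -> str:
        if fsf not in self.table.index:
            return NOT_ANNOTATED
        return str(self.table.loc[fsf, "subcategory"])

    def category(self, fsf: str) -> str:
        if fsf not in self.table.index:
            return NOT_ANNOTATED
        return str(self.table.loc[fsf, "category"])

    def annotated(self, fsfs: Iterable[str]) -> set[str]:
        return {f for f in fsfs if self.subcategory(f) != NOT_ANNOTATED}

    @property
    def subcategories(self) -> list[str]:
        return sorted(set(self.table["subcategory"]) - {NOT_ANNOTATED})


@dataclass
class EnrichmentResult:
    """One sub-category's enrichment in a sample against a background."""

    subcategory: str
    category: str
    k: int
    n: int
    M: int
    N: int
    p: Optional[float]  # None when the sample rate does not exceed background

    @property
    def rate_sample(self) -> float:
        return self.k / self.n

    @property
    def rate_background(self) -> float:
        return self.M / self.N

    @property
    def ratio(self) -> float:
        return self.rate_sample / self.rate_background

    @property
    def significant(self) -> bool:
        return self.p is not None and self.p < 0.05


def hypergeom_tail(N: int, M: int, n: int, k: int) -> float:
    """Exact upper-tail probability P(X >= k), X ~ Hypergeometric(N, M, n)."""
    _check_args(N, M, n, k)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, M, n))


def hypergeom_pmf(N: int, M: int, n: int, k: int) -> float:
    """Point mass P(X = k) (exposed separately from the tail used for tests)."""
    _check_args(N, M, n, k)
    return float(hypergeom.pmf(k, N, M, n))


def _check_args(N: int, M: int, n: int, k: int) -> None:
    if not (0 <= M <= N and 0 <= n <= N and 0 <= k <= min(n, M)):
        raise ValueError(
            f"invalid hypergeometric arguments N={N}, M={M}, n={n}, k={k}"
        )


def enrich(
    sample: set[str],
    background: set[str],
    fmap: FunctionMap,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Per-sub-category enrichment of ``sample`` within ``background``.

    Unannotated FSFs are excluded from both n and N.  P values are computed
    only for sub-categories over-represented in the sample (k/n > M/N).
    With ``bh_correct`` the tested P values are Benjamini-Hochberg adjusted.
    """
    if not sample <= background:
        raise ValueError("sample must be a subset of the background")
    sample_a = fmap.annotated(sample)
    bkgd_a = fmap.annotated(background)
    n, N = len(sample_a), len(bkgd_a)
    if n == 0 or N == 0:
        raise ValueError("no annotated FSFs to test")
    results: list[EnrichmentResult] = []
    for sub in fmap.subcategories:
        members = {f for f in bkgd_a if fmap.subcategory(f) == sub}
        M = len(members)
        k = len(members & sample_a)
        if k == 0:
            continue
        p = hypergeom_tail(N, M, n, k) if k / n > M / N else None
        cat = fmap.category(next(iter(members)))
        results.append(EnrichmentResult(sub, cat, k, n, M, N, p))
    if bh_correct:
        tested = [r for r in results if r.p is not None]
        order = sorted(tested, key=lambda r: r.p)
        m = len(order)
        adj = 0.0
        prev = 1.0
        for rank in range(m, 0, -1):
            r = order[rank - 1]
            prev = min(prev, r.p * m / rank)
            r.p = prev
    return sorted(results, key=lambda r: (r.p is None, r.p if r.p is not None else 0.0))


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Report table mirroring the published layout (ratios to 2 decimals)."""
    return pd.DataFrame(
        {
            "subcategory": [r.subcategory for r in results],
            "category": [r.category for r in results],
            "k": [r.k for r in results],
            "M": [r.M for r in results],
            "rate_sample": [round(r.rate_sample, 3) for r in results],
            "rate_background": [round(r.rate_background, 3) for r in results],
            "ratio": [round(r.ratio, 2) for r in results],
            "p": [r.p for r in results],
        }
    )


def function_character_matrix(
    m: AbundanceMatrix, fmap: FunctionMap, n_states: int = 24
) -> CharacterMatrix:
    """Character matrix of functional sub-categories (characters) x proteomes.

    Each raw cell counts the distinct FSFs of a sub-category present in a
    proteome; cells are then recoded with the same ordered-state transform
    used for abundance characters.
    """
    counts = function_counts(m, fmap)
    from .census_io import AbundanceMatrix as AM

    pseudo = AM(g=counts, meta=m.meta.copy())
    return recode(pseudo, n_states=n_states, scale="linear")


def function_counts(m: AbundanceMatrix, fmap: FunctionMap) -> pd.DataFrame:
    """Distinct-FSF counts per (sub-category, proteome), before recoding."""
    subs = fmap.subcategories
    present = m.g > 0
    data = {}
    sub_of = {f: fmap.subcategory(f) for f in m.fsfs}
    for p in m.proteomes:
        here = [f for f in m.fsfs if present.loc[f, p]]
        counts = {s: 0 for s in subs}
        for f in here:
            s = sub_of[f]
            if s != NOT_ANNOTATED and s in counts:
                counts[s] += 1
        data[p] = [counts[s] for s in subs]
    return pd.DataFrame(data, index=subs)


def function_diversity(m: AbundanceMatrix, fmap: FunctionMap) -> pd.Series:
    """Number of distinct annotated sub-categories per proteome."""
    counts = function_counts(m, fmap)
    return (counts > 0).sum(axis=0)
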