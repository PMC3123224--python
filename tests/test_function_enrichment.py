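"""Hypergeometric enrichment and function-character matrices."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from urproteome.census_io import AbundanceMatrix
from urproteome.function_enrichment import (
    FunctionMap,
    enrich,
    enrichment_table,
    function_character_matrix,
    function_counts,
    function_diversity,
    hypergeom_pmf,
    hypergeom_tail,
)


class TestHypergeomTail:
    def test_zero_successes_certain(self):
        assert hypergeom_tail(100, 10, 20, 0) == 1.0

    def test_small_case_exact_fraction(self):
        # C(2,2)*C(3,0)/C(5,2) = 1/10
        assert hypergeom_tail(5, 2, 2, 2) == pytest.approx(0.1, abs=1e-12)

    def test_tail_is_sum_of_pmf_terms(self):
        N, M, n = 60, 12, 15
        for k in range(0, 13):
            direct = sum(
                math.comb(M, j) * math.comb(N - M, n - j) / math.comb(N, n)
                for j in range(k, min(n, M) + 1)
            )
            assert hypergeom_tail(N, M, n, k) == pytest.approx(direct, rel=1e-10)

    def test_pmf_sums_to_one_exactly(self):
        for N, M, n in [(20, 5, 7), (200, 40, 60), (150, 150, 10)]:
            total = sum(hypergeom_pmf(N, M, n, k) for k in range(max(0, n + M - N), min(n, M) + 1))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_monotone_nonincreasing_in_k(self):
        vals = [hypergeom_tail(500, 50, 60, k) for k in range(0, 30)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_binomial_envelope_for_small_sampling_fraction(self):
        from scipy.stats import binom

        N, M, n = 4000, 400, 100  # n/N = 0.025
        mean = n * M / N
        sd = math.sqrt(mean * (1 - M / N))
        for k in range(int(mean), int(mean + 3 * sd)):
            h = hypergeom_tail(N, M, n, k)
            b = float(binom.sf(k - 1, n, M / N))
            assert abs(h - b) / h < 0.25

    def test_bounds_validated(self):
        for bad in [(10, 20, 5, 1), (10, 5, 20, 1), (10, 5, 5, 6)]:
            with pytest.raises(ValueError):
                hypergeom_tail(*bad)


def published_style_sets():
    """Background of 1,420 FSFs (4 unannotated) with sub-category counts and
    two nested samples reproducing the published contingency layout."""
    fsfs = [f"x.{i}.1" for i in range(1420)]
    mapping = {}
    cursor = 0

    def take(n):
        nonlocal cursor
        out = fsfs[cursor : cursor + n]
        cursor += n
        return out

    groups = {
        ("Metabolism", "transferases"): 29,
        ("General", "small molecule binding"): 22,
        ("Metabolism", "nucleotide m/tr"): 29,
        ("Information", "translation"): 89,
    }
    pools = {}
    for (cat, sub), M in groups.items():
        pools[sub] = take(M)
        for f in pools[sub]:
            mapping[f] = (cat, sub)
    rest = take(1416 - sum(groups.values()))
    for f in rest:
        mapping[f] = ("Metabolism", "other enzymes")
    # 4 left unannotated
    fmap = FunctionMap.from_dict(mapping)
    background = set(fsfs)

    min_set = set(
        pools["transferases"][:6]
        + pools["small molecule binding"][:4]
        + pools["nucleotide m/tr"][:7]
        + rest[:53]
    )
    max_set = set(
        pools["translation"][:34] + pools["nucleotide m/tr"][:8] + rest[:110]
    )
    assert len(min_set) == 70 and len(max_set) == 152
    return fmap, background, min_set, max_set


class TestEnrich:
    def test_sample_equals_background_is_null(self):
        fmap = FunctionMap.from_dict(
            {f"f{i}": ("Metabolism", "redox" if i < 3 else "energy") for i in range(8)}
        )
        results = enrich(set(fmap.table.index), set(fmap.table.index), fmap)
        assert all(r.ratio == 1.0 and r.p is None for r in results)

    def test_published_layout_ratios_and_tails(self):
        fmap, background, min_set, max_set = published_style_sets()
        by_sub = {r.subcategory: r for r in enrich(min_set, background, fmap)}
        assert by_sub["transferases"].N == 1416 and by_sub["transferases"].n == 70
        assert round(by_sub["transferases"].ratio, 2) == 4.19
        assert round(by_sub["small molecule binding"].ratio, 2) == 3.68
        assert round(by_sub["nucleotide m/tr"].ratio, 2) == 4.88
        assert by_sub["transferases"].p == pytest.approx(
            hypergeom.sf(5, 1416, 29, 70)
        )
        mx = {r.subcategory: r for r in enrich(max_set, background, fmap)}
        assert round(mx["translation"].ratio, 2) == 3.56
        assert round(mx["nucleotide m/tr"].ratio, 2) == 2.57

    def test_sample_must_be_subset(self):
        fmap = FunctionMap.from_dict({"f0": ("Other", "unknown function")})
        with pytest.raises(ValueError):
            enrich({"f1"}, {"f0"}, fmap)

    def test_unannotated_excluded_from_both_counts(self):
        fmap = FunctionMap.from_dict({"f0": ("Metabolism", "redox"), "f1": ("Metabolism", "redox")})
        results = enrich({"f0", "fx"}, {"f0", "f1", "fx", "fy"}, fmap)
        (r,) = results
        assert r.n == 1 and r.N == 2

    def test_null_false_positive_rate_matches_exact_enumeration(self):
        N, M, n = 400, 100, 100
        # oracle: exact probability that a null draw is called significant
        q = sum(
            hypergeom.pmf(k, N, M, n)
            for k in range(0, min(n, M) + 1)
            if k / n > M / N and hypergeom.sf(k - 1, N, M, n) < 0.05
        )
        fsfs = [f"f{i}" for i in range(N)]
        fmap = FunctionMap.from_dict(
            {f: ("Metabolism", "redox" if i < M else "energy") for i, f in enumerate(fsfs)}
        )
        rng = np.random.default_rng(123)
        trials, hits = 400, 0
        for _ in range(trials):
            sample = set(rng.choice(fsfs, size=n, replace=False))
            res = {r.subcategory: r for r in enrich(sample, set(fsfs), fmap)}
            r = res.get("redox")
            if r is not None and r.significant:
                hits += 1
        se = math.sqrt(q * (1 - q) / trials)
        assert abs(hits / trials - q) <= 4 * se + 1e-9

    def test_bh_correction_weakly_increases_p(self):
        fmap, background, min_set, _ = published_style_sets()
        raw = {r.subcategory: r.p for r in enrich(min_set, background, fmap) if r.p}
        adj = {r.subcategory: r.p for r in enrich(min_set, background, fmap, bh_correct=True) if r.p}
        for sub in raw:
            assert adj[sub] >= raw[sub] - 1e-12


@pytest.fixture
def function_matrix():
    g = pd.DataFrame(
        {
            "P1": [2, 1, 1, 0, 5],
            "P2": [0, 0, 3, 1, 0],
        },
        index=["t1", "t2", "r1", "r2", "u1"],
    )
    meta = pd.DataFrame(
        {"superkingdom": ["A", "B"], "lifestyle": ["FL", "FL"]}, index=["P1", "P2"]
    )
    fmap = FunctionMap.from_dict(
        {
            "t1": ("Information", "translation"),
            "t2": ("Information", "translation"),
            "r1": ("Metabolism", "redox"),
            "r2": ("Metabolism", "redox"),
            # u1 unannotated
        }
    )
    return AbundanceMatrix(g=g, meta=meta), fmap


class TestFunctionMatrix:
    def test_counts_distinct_fsfs(self, function_matrix):
        m, fmap = function_matrix
        counts = function_counts(m, fmap)
        assert counts.loc["translation", "P1"] == 2
        assert counts.loc["translation", "P2"] == 0
        assert counts.loc["redox", "P2"] == 2

    def test_recoded_matrix_hand_example(self, function_matrix):
        m, fmap = function_matrix
        cm = function_character_matrix(m, fmap)
        assert cm.taxa == ["P1", "P2"]
        assert set(cm.characters) == {"translation", "redox"}
        # raw counts max is 2 -> states are round(c/2*23)
        j = cm.characters.index("translation")
        assert cm.states[0, j] == 23 and cm.states[1, j] == 0

    def test_diversity_counts_subcategories(self, function_matrix):
        m, fmap = function_matrix
        div = function_diversity(m, fmap)
        assert div["P1"] == 2  # translation + redox; unannotated ignored
        assert div["P2"] == 1  # redox only (both redox FSFs share the sub-category)

    def test_diversity_matches_set_union_oracle(self, function_matrix):
        m, fmap = function_matrix
        div = function_diversity(m, fmap)
        for p in m.proteomes:
            expected = {
                fmap.subcategory(f)
                for f in m.fsfs
                if m.g.loc[f, p] > 0 and fmap.subcategory(f) != "not annotated"
            }
            assert div[p] == len(expected)


def test_enrichment_table_layout():
    fmap, background, min_set, _ = published_style_sets()
    table = enrichment_table(enrich(min_set, background, fmap))
    assert {"subcategory", "k", "M", "ratio", "p"} <= set(table.columns)
    row = table[table.subcategory == "transferases"].iloc[0]
    assert row.ratio == 4.19
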