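"""Hypergeometric co-citation statistic against independent oracles."""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from mirsig.association import (
    CooccurrenceTable,
    cocitation_pvalue,
    hypergeometric_pmf,
    screen_genes,
)


def exact_tail(k: int, n: int, m: int, N: int) -> Fraction:
    """Exact upper tail by rational combinatorial summation."""
    total = math.comb(N, m)
    return Fraction(
        sum(math.comb(n, i) * math.comb(N - n, m - i)
            for i in range(max(k, max(0, n + m - N)), min(n, m) + 1)),
        total,
    )


def enumerated_tail(k: int, n: int, m: int, N: int) -> Fraction:
    """Brute-force tail: enumerate every placement of the m gene articles."""
    hits = 0
    total = 0
    disease = set(range(n))
    for combo in itertools.combinations(range(N), m):
        total += 1
        if sum(1 for a in combo if a in disease) >= k:
            hits += 1
    return Fraction(hits, total)


def test_pmf_direct_combinatorial_value():
    # C(5,3)*C(15,1)/C(20,4) = 150/4845
    assert hypergeometric_pmf(3, n=5, m=4, N=20) == pytest.approx(150 / 4845, abs=1e-15)


def test_pmf_degenerate_and_normalization():
    assert hypergeometric_pmf(0, n=0, m=5, N=10) == 1.0
    assert hypergeometric_pmf(1, n=0, m=5, N=10) == 0.0
    total = sum(hypergeometric_pmf(i, n=5, m=4, N=20) for i in range(0, 5))
    assert total == pytest.approx(1.0, abs=1e-12)


def test_pmf_matches_scipy_cross_check():
    for n, m, N in [(5, 4, 20), (30, 12, 60), (0, 7, 9), (600, 40, 2000)]:
        for i in range(0, min(n, m) + 1):
            assert hypergeometric_pmf(i, n, m, N) == pytest.approx(
                float(hypergeom.pmf(i, N, n, m)), rel=1e-10, abs=1e-300
            )


def test_pvalue_worked_example():
    # (150 + 5) / 4845
    assert cocitation_pvalue(3, n=5, m=4, N=20) == pytest.approx(155 / 4845, abs=1e-12)


def test_pvalue_boundaries():
    assert cocitation_pvalue(0, n=5, m=4, N=20) == 1.0
    assert cocitation_pvalue(min(5, 4) + 1, n=5, m=4, N=20) == 0.0


def test_pvalue_matches_brute_force_enumeration():
    """Exhaustive enumeration of article placements on small corpora."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        N = int(rng.integers(2, 13))
        n = int(rng.integers(0, N + 1))
        m = int(rng.integers(0, min(N, 6) + 1))
        for k in range(0, min(n, m) + 2):
            expected = float(enumerated_tail(k, n, m, N))
            assert cocitation_pvalue(k, n, m, N) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_pvalue_matches_exact_fraction_all_small_corpora(data):
    """For N <= 25 the log-gamma tail equals the exact rational tail to 1e-12."""
    N = data.draw(st.integers(1, 25))
    n = data.draw(st.integers(0, N))
    m = data.draw(st.integers(0, N))
    k = data.draw(st.integers(0, min(n, m) + 1))
    assert cocitation_pvalue(k, n, m, N) == pytest.approx(
        float(exact_tail(k, n, m, N)), abs=1e-12
    )


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(1, 200))
def test_tail_identity_and_monotonicity(seed):
    rng = np.random.default_rng(seed)
    N = int(rng.integers(5, 500))
    n = int(rng.integers(0, N + 1))
    m = int(rng.integers(0, N + 1))
    tails = [cocitation_pvalue(k, n, m, N) for k in range(0, min(n, m) + 2)]
    # monotone non-increasing in k
    assert all(a >= b - 1e-12 for a, b in zip(tails, tails[1:]))
    # tail identity: P(X >= k) + sum_{i<k} pmf(i) = 1
    for k in range(0, min(n, m) + 2):
        head = sum(hypergeometric_pmf(i, n, m, N) for i in range(k))
        assert tails[k] + head == pytest.approx(1.0, abs=1e-9)


def test_large_corpus_no_overflow():
    p = cocitation_pvalue(k=500, n=64577, m=1200, N=5_000_000)
    assert 0.0 <= p <= 1.0
    assert p == pytest.approx(float(hypergeom.sf(499, 5_000_000, 64577, 1200)), rel=1e-6)


def test_domain_errors():
    with pytest.raises(ValueError):
        hypergeometric_pmf(1, n=-1, m=2, N=5)
    with pytest.raises(ValueError):
        cocitation_pvalue(1, n=6, m=2, N=5)
    table = CooccurrenceTable(N=10, n=5, counts=pd.DataFrame({"gene": ["A"], "m": [4], "k": [3]}))
    with pytest.raises(ValueError):
        screen_genes(table, alpha=0.0)


def test_count_invariants_rejected():
    with pytest.raises(ValueError):
        CooccurrenceTable(N=10, n=2, counts=pd.DataFrame({"gene": ["A"], "m": [4], "k": [3]}))


def test_screen_sorting_and_ties():
    counts = pd.DataFrame(
        {"gene": ["ZZZ", "AAA", "MMM"], "m": [4, 4, 1], "k": [3, 3, 0]}
    )
    table = CooccurrenceTable(N=20, n=5, counts=counts)
    records = screen_genes(table, alpha=1.0)
    # identical counts -> identical p, adjacent, lexicographic order
    assert [r.gene for r in records] == ["AAA", "ZZZ", "MMM"]
    assert records[0].p == records[1].p
    # a gene with k=0 has p=1 and never passes alpha < 1
    assert not [r for r in screen_genes(table, alpha=0.99) if r.gene == "MMM"]


def test_benjamini_hochberg_adjustment_is_monotone():
    counts = pd.DataFrame(
        {"gene": [f"G{i}" for i in range(6)], "m": [10] * 6, "k": [9, 7, 5, 3, 1, 0]}
    )
    table = CooccurrenceTable(N=100, n=30, counts=counts)
    raw = {r.gene: r.p for r in screen_genes(table, alpha=1.0)}
    adj = {r.gene: r.p_adjusted for r in screen_genes(table, alpha=1.0, correction="benjamini_hochberg")}
    assert all(adj[g] >= raw[g] - 1e-15 for g in raw)
    assert all(0.0 <= v <= 1.0 for v in adj.values())
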