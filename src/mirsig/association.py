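"""Co-citation association statistics.

The association between a gene and a disease is scored from literature
counts alone.  With ``N`` articles in the corpus, ``n`` of them mentioning
the disease, ``m`` mentioning the gene and ``k`` mentioning both, the
null model is that the ``m`` gene articles are an unordered sample drawn
from the corpus without replacement, independently of the disease label.
The number of co-mention articles then follows the hypergeometric
distribution, and the association evidence is the upper tail

    p = P(X >= k) = 1 - sum_{i<k} p(i | n, m, N)

Small p means the gene and the disease co-occur in more articles than
random sampling would produce.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CooccurrenceTable",
    "AssociationRecord",
    "Correction",
    "hypergeometric_pmf",
    "cocitation_pvalue",
    "screen_genes",
]


class Correction(str, Enum):
    """Multiple-testing correction applied when screening genes."""

    none = "none"
    benjamini_hochberg = "benjamini_hochberg"


@dataclass(frozen=True)
class CooccurrenceTable:
    """Per-gene document-frequency counts against a disease.

    Parameters
    ----------
    N : int
        Total number of articles in the corpus.
    n : int
        Number of disease-relevant articles.
    counts : pandas.DataFrame
        One row per gene with columns ``gene``, ``m`` (articles mentioning
        the gene) and ``k`` (articles mentioning the gene and the disease).
    article_mentions : list of (set, bool) or None
        Optional per-article mention sets with the disease flag, retained
        so gene-gene co-citation edges can be derived later.
    """

    N: int
    n: int
    counts: pd.DataFrame
    article_mentions: list | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n <= self.N:
            raise ValueError(f"need 0 <= n <= N, got n={self.n}, N={self.N}")
        c = self.counts
        for col in ("gene", "m", "k"):
            if col not in c.columns:
                raise ValueError(f"counts table lacks column {col!r}")
        if len(c) and not (
            (c["k"] >= 0).all()
            and (c["k"] <= np.minimum(c["m"], self.n)).all()
            and (c["m"] <= self.N).all()
        ):
            raise ValueError("count invariants violated: need 0 <= k <= min(n, m) and m <= N")


@dataclass(frozen=True)
class AssociationRecord:
    """One gene's co-citation counts and tail probability."""

    gene: str
    N: int
    n: int
    m: int
    k: int
    p: float
    p_adjusted: float


def _check_domain(n: int, m: int, N: int) -> None:
    if min(n, m, N) < 0:
        raise ValueError(f"counts must be non-negative, got n={n}, m={m}, N={N}")
    if n > N or m > N:
        raise ValueError(f"need n <= N and m <= N, got n={n}, m={m}, N={N}")


def _log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def hypergeometric_pmf(i: int, n: int, m: int, N: int) -> float:
    """Probability that exactly ``i`` of the ``m`` gene articles are disease articles.

    Evaluates C(n, i) * C(N - n, m - i) / C(N, m) in log space so corpora
    with millions of articles do not overflow.  Outside the support
    ``max(0, n + m - N) <= i <= min(n, m)`` the mass is 0.
    """
    _check_domain(n, m, N)
    if i < max(0, n + m - N) or i > min(n, m):
        return 0.0
    log_p = (
        _log_comb(np.float64(n), np.float64(i))
        + _log_comb(np.float64(N - n), np.float64(m - i))
        - _log_comb(np.float64(N), np.float64(m))
    )
    return float(np.exp(log_p))


def cocitation_pvalue(k: int, n: int, m: int, N: int) -> float:
    """Upper-tail co-citation probability P(X >= k).

    Identical to 1 - sum_{i=0}^{k-1} p(i | n, m, N); the tail is summed
    directly over the support so small probabilities keep relative
    accuracy.  Returns exactly 1.0 when k == 0 and 0.0 beyond the support.
    """
    _check_domain(n, m, N)
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    if k == 0:
        return 1.0
    hi = min(n, m)
    if k > hi:
        return 0.0
    i = np.arange(max(k, max(0, n + m - N)), hi + 1, dtype=np.float64)
    log_terms = (
        _log_comb(np.float64(n), i)
        + _log_comb(np.float64(N - n), np.float64(m) - i)
        - _log_comb(np.float64(N), np.float64(m))
    )
    # log-sum-exp keeps the sum stable when individual terms underflow
    peak = log_terms.max()
    tail = float(np.exp(peak) * np.exp(log_terms - peak).sum())
    return min(1.0, max(0.0, tail))


def screen_genes(
    table: CooccurrenceTable,
    alpha: float = 0.05,
    correction: Correction | str = Correction.none,
) -> list[AssociationRecord]:
    """Score every gene in the table and keep those significant at ``alpha``.

    Returns records with (adjusted, if requested) p <= alpha, sorted by
    ascending p with lexicographic gene-symbol tie-break.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    correction = Correction(correction)
    rows = table.counts
    pvals = np.array(
        [cocitation_pvalue(int(k), table.n, int(m), table.N) for m, k in zip(rows["m"], rows["k"])]
    )
    if correction is Correction.benjamini_hochberg and len(pvals):
        adjusted = multipletests(pvals, method="fdr_bh")[1]
    else:
        adjusted = pvals.copy()
    records = [
        AssociationRecord(str(g), table.N, table.n, int(m), int(k), float(p), float(pa))
        for g, m, k, p, pa in zip(rows["gene"], rows["m"], rows["k"], pvals, adjusted)
    ]
    kept = [r for r in records if r.p_adjusted <= alpha]
    kept.sort(key=lambda r: (r.p_adjusted, r.p, r.gene))
    return kept


def association_table(table: CooccurrenceTable, correction: Correction | str = Correction.none,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Full per-gene association table (no filtering), as written to disk."""
    correction = Correction(correction)
    rows = table.counts
    pvals = np.array(
        [cocitation_pvalue(int(k), table.n, int(m), table.N) for m, k in zip(rows["m"], rows["k"])]
    ) if len(rows) else np.array([])
    if correction is Correction.benjamini_hochberg and len(pvals):
        adjusted = multipletests(pvals, method="fdr_bh")[1]
    else:
        adjusted = pvals.copy()
    out = pd.DataFrame(
        {
            "gene": rows["gene"].astype(str),
            "N": table.N,
            "n": table.n,
            "m": rows["m"].astype(int),
            "k": rows["k"].astype(int),
            "p": pvals,
            "p_adjusted": adjusted,
        }
    )
    out["significant"] = out["p_adjusted"] <= alpha
    out = out.sort_values(["p_adjusted", "p", "gene"], kind="mergesort").reset_index(drop=True)
    return out


def genes_from_records(records: Iterable[AssociationRecord]) -> list[str]:
    return sorted({r.gene for r in records})
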