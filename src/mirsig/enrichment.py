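"""Gene-set over-representation analysis.

A query gene set is tested against named gene sets (GO categories per
namespace, or pathways) under the hypergeometric model: the query is
treated as a draw without replacement from the annotation universe, and
the over-representation p-value is the upper tail P(X >= overlap).
This equals the one-sided Fisher exact test on the 2x2 table.  The
universe is the set of all genes annotated in the loaded database; query
genes outside it are dropped (and counted) before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import pandas as pd

from .association import cocitation_pvalue

__all__ = ["Namespace", "GeneSetDB", "EnrichmentRecord", "classify_go", "enrich_pathways"]

log = logging.getLogger(__name__)


class Namespace(str, Enum):
    molecular_function = "molecular_function"
    cellular_component = "cellular_component"
    biological_process = "biological_process"
    pathway = "pathway"


GO_NAMESPACES = (
    Namespace.molecular_function,
    Namespace.cellular_component,
    Namespace.biological_process,
)


@dataclass
class GeneSetDB:
    """Named gene sets with namespace labels and an annotation universe."""

    sets: dict[str, set[str]]
    namespace: dict[str, Namespace]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, members in self.sets.items():
            if name not in self.namespace:
                raise ValueError(f"set {name!r} has no namespace label")
            outside = members - self.universe
            if outside:
                raise ValueError(f"set {name!r} has members outside the universe: {sorted(outside)[:5]}")
        self.namespace = {k: Namespace(v) for k, v in self.namespace.items()}

    def subset(self, names: Iterable[str]) -> "GeneSetDB":
        names = [n for n in names if n in self.sets]
        return GeneSetDB(
            sets={n: set(self.sets[n]) for n in names},
            namespace={n: self.namespace[n] for n in names},
            universe=set(self.universe),
        )

    def by_namespace(self, namespace: Namespace) -> list[str]:
        return sorted(n for n, ns in self.namespace.items() if ns is Namespace(namespace))


@dataclass(frozen=True)
class EnrichmentRecord:
    """Over-representation result for one named set."""

    name: str
    namespace: Namespace
    count: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    significant: bool


def _enrich_one(query: set[str], members: set[str], universe_size: int) -> tuple[int, float]:
    count = len(query & members)
    if count == 0:
        return 0, 1.0
    # draw |query| genes from the universe; |members| are in the category
    p = cocitation_pvalue(k=count, n=len(members), m=len(query), N=universe_size)
    return count, p


def _restrict_query(query: Iterable[str], db: GeneSetDB) -> set[str]:
    query = set(query)
    kept = query & db.universe
    dropped = len(query) - len(kept)
    if dropped:
        log.info("dropped %d query gene(s) outside the annotation universe", dropped)
    return kept


def classify_go(query: Iterable[str], db: GeneSetDB, alpha: float = 0.05) -> list[EnrichmentRecord]:
    """Classify a query set across the three GO namespaces.

    One record per category, in namespace order then database order, with
    the overlap count and hypergeometric over-representation p-value.
    Categories with no overlap are reported with p = 1.
    """
    if not db.universe:
        raise ValueError("empty annotation universe")
    q = _restrict_query(query, db)
    records = []
    for ns in GO_NAMESPACES:
        for name in db.by_namespace(ns):
            count, p = _enrich_one(q, db.sets[name], len(db.universe))
            records.append(
                EnrichmentRecord(name, ns, count, len(db.sets[name]), len(q),
                                 len(db.universe), p, p <= alpha)
            )
    return records


def enrich_pathways(query: Iterable[str], db: GeneSetDB, alpha: float = 0.05) -> list[EnrichmentRecord]:
    """Pathway over-representation, sorted by ascending p (gene-set name tie-break)."""
    if not db.universe:
        raise ValueError("empty annotation universe")
    q = _restrict_query(query, db)
    records = []
    for name in db.by_namespace(Namespace.pathway):
        count, p = _enrich_one(q, db.sets[name], len(db.universe))
        records.append(
            EnrichmentRecord(name, Namespace.pathway, count, len(db.sets[name]), len(q),
                             len(db.universe), p, p <= alpha)
        )
    records.sort(key=lambda r: (r.p, r.name))
    return records


def enrichment_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "namespace": r.namespace.value,
                "set": r.name,
                "count": r.count,
                "set_size": r.set_size,
                "p": r.p,
                "significant": r.significant,
            }
            for r in records
        ],
        columns=["namespace", "set", "count", "set_size", "p", "significant"],
    )
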