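"""Typed gene interaction networks, connectivity, and hub scoring.

Edges carry a relation class (KEGG-style ECrel / PPrel / GErel,
experimental PPI, or literature co-citation) and a provenance label, but
degree is counted over distinct neighbors: several typed edges between
the same gene pair contribute a single interaction partner, matching how
connectivity is read off an integrated network.  Hubs are scored by the
degree standard score against the network's own degree distribution,
with a one-sided upper normal tail.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import norm

from .association import CooccurrenceTable, cocitation_pvalue

__all__ = [
    "RelationClass",
    "Provenance",
    "TypedEdge",
    "InteractionGraph",
    "HubRecord",
    "build_graph",
    "literature_edges",
    "connectivity",
    "hub_ztest",
]

log = logging.getLogger(__name__)


class RelationClass(str, Enum):
    ECrel = "ECrel"          # enzyme-enzyme: successive catalytic steps
    PPrel = "PPrel"          # protein-protein: binding / modification
    GErel = "GErel"          # transcription factor -> target gene expression
    PPI = "PPI"              # experimental protein-protein interaction
    literature = "literature"  # significant gene-gene co-citation


class Provenance(str, Enum):
    database = "database"
    experiment = "experiment"
    literature = "literature"


DEFAULT_PROVENANCE = {
    RelationClass.ECrel: Provenance.database,
    RelationClass.PPrel: Provenance.database,
    RelationClass.GErel: Provenance.database,
    RelationClass.PPI: Provenance.experiment,
    RelationClass.literature: Provenance.literature,
}


@dataclass(frozen=True)
class TypedEdge:
    """One undirected typed interaction between two genes."""

    source: str
    target: str
    relation_class: RelationClass
    provenance: Provenance

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError(f"self-loop rejected: {self.source}")
        object.__setattr__(self, "relation_class", RelationClass(self.relation_class))
        object.__setattr__(self, "provenance", Provenance(self.provenance))

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.source, self.target)))


@dataclass
class InteractionGraph:
    """Undirected simple graph for connectivity, plus the typed edge records."""

    graph: nx.Graph
    edges: set[TypedEdge]

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def degree(self, gene: str) -> int:
        return int(self.graph.degree[gene])

    def degrees(self) -> dict[str, int]:
        return {g: int(d) for g, d in self.graph.degree}

    def neighbor_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def induced(self, nodes: Iterable[str]) -> "InteractionGraph":
        nodes = set(nodes)
        sub = self.graph.subgraph(nodes).copy()
        kept = {e for e in self.edges if e.source in nodes and e.target in nodes}
        return InteractionGraph(graph=sub, edges=kept)

    def edge_frame(self) -> pd.DataFrame:
        rows = sorted(
            (e.pair[0], e.relation_class.value, e.pair[1], e.provenance.value)
            for e in self.edges
        )
        return pd.DataFrame(rows, columns=["source", "relation_class", "target", "provenance"])


@dataclass(frozen=True)
class HubRecord:
    gene: str
    degree: int
    z: float
    p: float


def build_graph(
    edge_tables: Sequence[Iterable[TypedEdge]],
    node_universe: set[str] | None = None,
) -> InteractionGraph:
    """Union several typed edge sources into one interaction graph.

    Duplicate (pair, relation class) records collapse to one; when a
    ``node_universe`` is given, edges touching genes outside it are
    dropped with a logged count.
    """
    seen: dict[tuple[str, str, RelationClass], TypedEdge] = {}
    dropped = 0
    for table in edge_tables:
        for edge in table:
            if node_universe is not None and (
                edge.source not in node_universe or edge.target not in node_universe
            ):
                dropped += 1
                continue
            key = (*edge.pair, edge.relation_class)
            seen.setdefault(key, edge)
    if dropped:
        log.info("dropped %d edge(s) with an endpoint outside the node universe", dropped)
    g = nx.Graph()
    edges = set(seen.values())
    for edge in edges:
        g.add_edge(*edge.pair)
    return InteractionGraph(graph=g, edges=edges)


def literature_edges(table: CooccurrenceTable, alpha: float = 0.05) -> list[TypedEdge]:
    """Gene-gene co-citation edges from mined per-article mention sets.

    For each gene pair the same hypergeometric tail used for gene-disease
    association is applied with n = articles mentioning one gene, m =
    articles mentioning the other, k = co-mention articles; pairs with
    k >= 1 and p <= alpha become literature edges.
    """
    if table.article_mentions is None:
        raise ValueError("co-occurrence table lacks per-article mention sets")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    N = table.N
    m_count: dict[str, int] = {}
    pair_k: dict[tuple[str, str], int] = {}
    for mentions, _disease in table.article_mentions:
        for g in mentions:
            m_count[g] = m_count.get(g, 0) + 1
        for a, b in itertools.combinations(sorted(mentions), 2):
            pair_k[(a, b)] = pair_k.get((a, b), 0) + 1
    edges = []
    for (a, b), k in sorted(pair_k.items()):
        p = cocitation_pvalue(k=k, n=m_count[a], m=m_count[b], N=N)
        if p <= alpha:
            edges.append(TypedEdge(a, b, RelationClass.literature, Provenance.literature))
    return edges


def connectivity(graph: InteractionGraph) -> list[tuple[str, int]]:
    """(gene, degree) sorted by degree descending, symbol ascending."""
    return sorted(graph.degrees().items(), key=lambda t: (-t[1], t[0]))


def hub_ztest(graph: InteractionGraph, gene: str) -> HubRecord:
    """Degree standard score of one gene against the whole network.

    z = (degree - mean degree) / population sd of degrees; p is the
    one-sided upper normal tail.  A degree-regular network has sd 0, in
    which case z = 0 and p = 0.5 with a warning.
    """
    degrees = graph.degrees()
    if gene not in degrees:
        raise KeyError(f"gene {gene!r} not in graph")
    if len(degrees) < 2:
        raise ValueError("hub z-test needs a graph with at least 2 nodes")
    values = pd.Series(list(degrees.values()), dtype=float)
    sd = float(values.std(ddof=0))
    if sd == 0.0:
        warnings.warn("degree distribution is constant; hub z-test is undefined (z=0)")
        return HubRecord(gene, degrees[gene], 0.0, 0.5)
    z = (degrees[gene] - float(values.mean())) / sd
    return HubRecord(gene, degrees[gene], z, float(norm.sf(z)))


def hub_table(graph: InteractionGraph) -> pd.DataFrame:
    rows = [hub_ztest(graph, g) for g, _ in connectivity(graph)] if len(graph.nodes) >= 2 else []
    return pd.DataFrame(
        [{"gene": r.gene, "degree": r.degree, "z": r.z, "p": r.p} for r in rows],
        columns=["gene", "degree", "z", "p"],
    )
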