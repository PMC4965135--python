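"""Analytical integration of the disease signature and the target set.

The overlap signature is the exact intersection of the literature-derived
disease gene set and the consensus miRNA target set.  Each overlap gene
is then attributed to every significant pathway containing it (a gene
may sit in several), and the induced interaction subgraph on the overlap
is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .enrichment import GeneSetDB
from .network import InteractionGraph

__all__ = ["OverlapReport", "intersect_sets", "overlap_network"]


@dataclass
class OverlapReport:
    """Overlap signature with provenance and pathway attribution."""

    overlap: list[str]
    provenance: dict[str, dict] = field(default_factory=dict)  # gene -> {disease_p, n_votes}
    attribution: dict[str, list[str]] = field(default_factory=dict)  # pathway -> genes
    unattributed: list[str] = field(default_factory=list)
    subgraph: InteractionGraph | None = None

    def to_frame(self) -> pd.DataFrame:
        pathways_of: dict[str, list[str]] = {g: [] for g in self.overlap}
        for pathway, genes in self.attribution.items():
            for g in genes:
                pathways_of[g].append(pathway)
        rows = []
        for g in self.overlap:
            prov = self.provenance.get(g, {})
            rows.append(
                {
                    "gene": g,
                    "disease_p": prov.get("disease_p", ""),
                    "n_votes": prov.get("n_votes", ""),
                    "pathways": ",".join(sorted(pathways_of[g])),
                }
            )
        return pd.DataFrame(rows, columns=["gene", "disease_p", "n_votes", "pathways"])


def intersect_sets(disease_genes: Iterable[str], target_genes: Iterable[str]) -> list[str]:
    """Exact intersection of the two signatures, lexicographically ordered."""
    return sorted(set(disease_genes) & set(target_genes))


def overlap_network(
    overlap: Iterable[str],
    graph: InteractionGraph,
    significant_pathways: GeneSetDB,
    provenance: Mapping[str, Mapping] | None = None,
) -> OverlapReport:
    """Induced subgraph and pathway attribution for the overlap signature.

    Every overlap gene is attributed to each significant pathway whose
    member set contains it; genes in none are listed as unattributed.
    """
    overlap = sorted(set(overlap))
    attribution: dict[str, list[str]] = {}
    attributed: set[str] = set()
    for name in sorted(significant_pathways.sets):
        members = significant_pathways.sets[name]
        hits = [g for g in overlap if g in members]
        if hits:
            attribution[name] = hits
            attributed.update(hits)
    return OverlapReport(
        overlap=overlap,
        provenance={g: dict(provenance[g]) for g in overlap if g in provenance} if provenance else {},
        attribution=attribution,
        unattributed=[g for g in overlap if g not in attributed],
        subgraph=graph.induced(overlap),
    )
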