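"""Consensus voting over miRNA target-prediction tools.

Each prediction tool contributes an unweighted boolean nomination per
gene; a gene becomes a consensus target when at least ``min_votes``
tools nominate it (inclusive threshold).  Tool scores, ranks and
energies are deliberately ignored: the vote count is the statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .textmining import GeneLexicon

__all__ = ["PredictionMatrix", "ConsensusParams", "load_predictions", "consensus_targets"]


@dataclass(frozen=True)
class PredictionMatrix:
    """Gene x tool boolean nomination table for one miRNA.

    Genes never nominated by any tool are absent; rows therefore each
    carry at least one vote.
    """

    genes: list[str]
    tools: list[str]
    votes: np.ndarray  # bool, shape (len(genes), len(tools))

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in prediction matrix")
        if len(set(self.tools)) != len(self.tools):
            raise ValueError("duplicate tools in prediction matrix")
        if self.votes.shape != (len(self.genes), len(self.tools)):
            raise ValueError("votes shape does not match genes x tools")
        if len(self.genes) and not self.votes.any(axis=1).all():
            raise ValueError("prediction matrix contains a gene with zero votes")

    def vote_counts(self) -> pd.Series:
        return pd.Series(self.votes.sum(axis=1), index=self.genes, name="n_votes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.votes.astype(int), index=self.genes, columns=self.tools)


@dataclass(frozen=True)
class ConsensusParams:
    """Vote threshold for consensus membership (inclusive)."""

    min_votes: int = 4

    def __post_init__(self) -> None:
        if self.min_votes < 1:
            raise ValueError(f"min_votes must be >= 1, got {self.min_votes}")


def load_predictions(
    per_tool: Mapping[str, set[str] | list[str]],
    lexicon: GeneLexicon | None = None,
) -> PredictionMatrix:
    """Assemble a PredictionMatrix from per-tool gene lists.

    Gene symbols are normalized through ``lexicon`` when one is supplied;
    names the lexicon does not know pass through unchanged.
    """
    if not per_tool:
        raise ValueError("need at least one tool")
    tools = sorted(per_tool)
    normalized: dict[str, set[str]] = {}
    for tool in tools:
        names = set(per_tool[tool])
        if lexicon is not None:
            names = {lexicon.canonical(g) or g for g in names}
        normalized[tool] = names
    genes = sorted(set().union(*normalized.values()))
    if not genes:
        warnings.warn("all tool lists are empty; returning an empty prediction matrix")
    votes = np.zeros((len(genes), len(tools)), dtype=bool)
    index = {g: i for i, g in enumerate(genes)}
    for j, tool in enumerate(tools):
        for g in normalized[tool]:
            votes[index[g], j] = True
    return PredictionMatrix(genes=genes, tools=tools, votes=votes)


def consensus_targets(matrix: PredictionMatrix, params: ConsensusParams) -> list[str]:
    """Genes nominated by at least ``params.min_votes`` tools.

    Sorted by vote count descending, then gene symbol ascending.
    """
    if params.min_votes > len(matrix.tools):
        raise ValueError(
            f"min_votes={params.min_votes} exceeds tool count {len(matrix.tools)}"
        )
    counts = matrix.votes.sum(axis=1)
    kept = [(int(c), g) for g, c in zip(matrix.genes, counts) if c >= params.min_votes]
    kept.sort(key=lambda t: (-t[0], t[1]))
    return [g for _, g in kept]


def consensus_table(matrix: PredictionMatrix, params: ConsensusParams) -> pd.DataFrame:
    """Per-gene vote report restricted to the consensus set."""
    counts = matrix.votes.sum(axis=1)
    rows = []
    for g, c, row in zip(matrix.genes, counts, matrix.votes):
        if c >= params.min_votes:
            voted = [t for t, v in zip(matrix.tools, row) if v]
            rows.append({"gene": g, "n_votes": int(c), "tools": ",".join(voted)})
    out = pd.DataFrame(rows, columns=["gene", "n_votes", "tools"])
    if len(out):
        out = out.sort_values(["n_votes", "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)
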