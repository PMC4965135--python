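"""Synthetic corpora, predictor tables, and annotation/relation databases.

Every downstream stage (tagging, co-citation screening, consensus
voting, enrichment, network construction) is exercised against data with
known planted structure:

* a PubMed-like corpus in which each article is disease-relevant with a
  fixed probability and gene mention probabilities are lifted inside
  disease articles for a planted associated subset;
* per-tool target nominations drawn with per-tool sensitivity on a
  planted target set and a per-tool false-positive rate elsewhere;
* pathway gene sets honoring planted memberships, padded to size;
* a typed relation table of planted edges plus Erdős–Rényi background.

Article text is emitted as a token stream containing synonym spellings
and shared-stem slash conjunctions ("HG3/7"), so the tagging stage is
genuinely exercised rather than bypassed.  One global seed spawns four
independent sub-streams (corpus, predictions, annotations, edges), so
regenerating one table never perturbs the others.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import PredictionMatrix
from .enrichment import GeneSetDB, Namespace
from .network import DEFAULT_PROVENANCE, Provenance, RelationClass, TypedEdge
from .textmining import ArticleRecord, GeneLexicon

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "default_config",
    "synthetic_lexicon",
    "generate_corpus",
    "generate_predictions",
    "generate_annotation_db",
    "generate_interaction_db",
]

DISEASE_TERM = "hepatocellular carcinoma"

_FILLER = (
    "patients with advanced tumors were studied and expression of the marker was "
    "measured in resected tissue followed by survival analysis across the cohort"
).split()

_STEM_SUFFIX = re.compile(r"^([A-Za-z][A-Za-z0-9]*?[A-Za-z])(\d+)$")


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults are the package's study conditions.

    The corpus defaults (2000 articles, disease rate 0.3, per-gene
    mention rate 0.02, lift 5 on 20 planted genes) give planted genes an
    expected ~88 mentioning articles of which ~60 are disease articles,
    versus ~12 expected under the null — a strong but finite literature
    signal.  The predictor defaults (11 tools, sensitivity 0.8, false
    positive rate 0.05) mirror a consensus vote over many imperfect
    target predictors.
    """

    n_articles: int = 2000
    disease_rate: float = 0.3
    gene_universe: tuple[str, ...] = tuple(f"HG{i}" for i in range(1, 121))
    base_mention_rate: float = 0.02
    planted_assoc: Mapping[str, float] = field(
        default_factory=lambda: {f"HG{i}": 5.0 for i in range(1, 21)}
    )
    n_tools: int = 11
    tool_sensitivity: float | Sequence[float] = 0.8
    tool_fpr: float | Sequence[float] = 0.05
    planted_targets: tuple[str, ...] = tuple(f"HG{i}" for i in range(11, 41))
    pathway_sizes: tuple[int, ...] = (8, 8, 10, 12)
    planted_pathway_membership: Mapping[str, frozenset] = field(
        default_factory=lambda: {
            "PW1": frozenset({"HG11", "HG12", "HG13", "HG14", "HG15", "HG16"}),
            "PW2": frozenset({"HG14", "HG16", "HG17"}),
            "PW3": frozenset({"HG18", "HG19", "HG20"}),
        }
    )
    planted_edges: tuple[tuple[str, str, str], ...] = tuple(
        ("HG11", "PPrel", f"HG{i}") for i in range(12, 21)
    )
    edge_density: float = 0.01
    conjunction_rate: float = 0.25
    alias_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_articles < 1:
            raise ConfigurationError("n_articles must be positive")
        if not self.gene_universe:
            raise ConfigurationError("gene_universe is empty")
        if len(set(self.gene_universe)) != len(self.gene_universe):
            raise ConfigurationError("gene_universe has duplicate symbols")
        for name in ("disease_rate", "base_mention_rate", "edge_density",
                     "conjunction_rate", "alias_rate"):
            _check_prob(name, getattr(self, name))
        universe = set(self.gene_universe)
        for g, lift in self.planted_assoc.items():
            if g not in universe:
                raise ConfigurationError(f"planted associated gene {g!r} outside universe")
            if lift < 0:
                raise ConfigurationError(f"lift for {g!r} must be >= 0, got {lift}")
        if self.n_tools < 1:
            raise ConfigurationError("n_tools must be >= 1")
        for name in ("tool_sensitivity", "tool_fpr"):
            for v in np.atleast_1d(np.asarray(getattr(self, name), dtype=float)):
                _check_prob(name, float(v))
        if set(self.planted_targets) - universe:
            raise ConfigurationError("planted targets outside universe")
        for size in self.pathway_sizes:
            if size > len(self.gene_universe):
                raise ConfigurationError(f"pathway size {size} exceeds universe size")
        for name, members in self.planted_pathway_membership.items():
            if set(members) - universe:
                raise ConfigurationError(f"planted pathway {name!r} has genes outside universe")
        for s, _cls, t in self.planted_edges:
            if s not in universe or t not in universe:
                raise ConfigurationError("planted edge endpoint outside universe")

    def per_tool(self, value: float | Sequence[float]) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            arr = np.repeat(arr, self.n_tools)
        if arr.size != self.n_tools:
            raise ConfigurationError("per-tool probability list does not match n_tools")
        return arr


@dataclass
class SyntheticTruth:
    """Ground truth bookkeeping emitted alongside the synthetic corpus."""

    assoc_genes: set[str]
    target_genes: set[str]
    pathway_membership: dict[str, set[str]]
    edge_list: list[tuple[str, str, str]]
    article_mentions: list[set[str]] = field(default_factory=list)
    disease_flags: list[bool] = field(default_factory=list)


def _streams(config: SyntheticConfig) -> list[np.random.Generator]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


def synthetic_lexicon(config: SyntheticConfig) -> GeneLexicon:
    """Lexicon for the synthetic universe: each symbol plus one alias spelling."""
    return GeneLexicon({g: {g, f"{g}PROT"} for g in config.gene_universe})


def _article_text(
    rng: np.random.Generator,
    mentioned: list[str],
    disease: bool,
    config: SyntheticConfig,
) -> str:
    """Token stream embedding gene mentions as lexicon-matchable spellings."""
    remaining = list(mentioned)
    tokens: list[str] = []
    consumed: set[str] = set()
    # conjunction pass: merge adjacent shared-stem numeric pairs into slash tokens
    i = 0
    while i + 1 < len(remaining):
        a, b = remaining[i], remaining[i + 1]
        ma, mb = _STEM_SUFFIX.match(a), _STEM_SUFFIX.match(b)
        if (
            ma is not None
            and mb is not None
            and ma.group(1) == mb.group(1)
            and rng.random() < config.conjunction_rate
        ):
            tokens.append(f"{ma.group(1)}{ma.group(2)}/{mb.group(2)}")
            consumed.update({a, b})
            i += 2
        else:
            i += 1
    for g in remaining:
        if g in consumed:
            continue
        tokens.append(f"{g}PROT" if rng.random() < config.alias_rate else g)
    if disease:
        tokens.append(DISEASE_TERM)
    filler = list(rng.choice(_FILLER, size=6))
    order = rng.permutation(len(tokens))
    body = []
    for idx, j in enumerate(order):
        body.append(tokens[j])
        body.append(filler[idx % len(filler)])
    return " ".join(body)


def generate_corpus(config: SyntheticConfig) -> tuple[list[ArticleRecord], SyntheticTruth]:
    """Generate the article corpus and its ground truth.

    Each article is independently disease-flagged with ``disease_rate``;
    gene g is mentioned with probability ``base_mention_rate`` in
    non-disease articles and ``min(1, base_mention_rate * lift(g))`` in
    disease articles.
    """
    rng = _streams(config)[0]
    genes = list(config.gene_universe)
    lifts = np.array([config.planted_assoc.get(g, 1.0) for g in genes])
    p_null = np.full(len(genes), config.base_mention_rate)
    p_disease = np.minimum(1.0, config.base_mention_rate * lifts)
    articles: list[ArticleRecord] = []
    truth = SyntheticTruth(
        assoc_genes={g for g, lift in config.planted_assoc.items() if lift > 1.0},
        target_genes=set(config.planted_targets),
        pathway_membership={k: set(v) for k, v in config.planted_pathway_membership.items()},
        edge_list=list(config.planted_edges),
    )
    for idx in range(config.n_articles):
        disease = bool(rng.random() < config.disease_rate)
        probs = p_disease if disease else p_null
        mask = rng.random(len(genes)) < probs
        mentioned = [g for g, hit in zip(genes, mask) if hit]
        text = _article_text(rng, mentioned, disease, config)
        articles.append(ArticleRecord(id=f"A{idx:06d}", text=text, disease_flag=disease))
        truth.article_mentions.append(set(mentioned))
        truth.disease_flags.append(disease)
    return articles, truth


def generate_predictions(config: SyntheticConfig, truth: SyntheticTruth) -> PredictionMatrix:
    """Per-tool target nominations over the gene universe.

    Tool t nominates each planted target with ``tool_sensitivity[t]`` and
    each non-target with ``tool_fpr[t]``, independently.  Genes no tool
    nominates are absent from the matrix.
    """
    rng = _streams(config)[1]
    sens = config.per_tool(config.tool_sensitivity)
    fpr = config.per_tool(config.tool_fpr)
    genes = list(config.gene_universe)
    is_target = np.array([g in truth.target_genes for g in genes])
    probs = np.where(is_target[:, None], sens[None, :], fpr[None, :])
    votes = rng.random(probs.shape) < probs
    keep = votes.any(axis=1)
    kept_genes = [g for g, k in zip(genes, keep) if k]
    order = np.argsort(kept_genes)  # lexicographic, matching load_predictions
    return PredictionMatrix(
        genes=[kept_genes[i] for i in order],
        tools=[f"tool{t + 1:02d}" for t in range(config.n_tools)],
        votes=votes[keep][order],
    )


def generate_annotation_db(config: SyntheticConfig, truth: SyntheticTruth) -> GeneSetDB:
    """Pathway gene sets honoring planted memberships, padded to the configured sizes.

    Pathways beyond the planted ones are filled entirely with random
    draws from the universe.  The annotation universe is the whole gene
    universe.
    """
    rng = _streams(config)[2]
    universe = list(config.gene_universe)
    planted_names = sorted(config.planted_pathway_membership)
    sets: dict[str, set[str]] = {}
    for i, size in enumerate(config.pathway_sizes):
        if i < len(planted_names):
            name = planted_names[i]
            members = set(config.planted_pathway_membership[name])
            if size < len(members):
                raise ConfigurationError(
                    f"pathway size {size} smaller than planted membership of {name!r}"
                )
        else:
            name = f"PW{i + 1}"
            members = set()
        pool = [g for g in universe if g not in members and g not in truth.target_genes]
        rng.shuffle(pool)
        need = size - len(members)
        if need > len(pool):
            # fall back to any non-member when decoy pool is exhausted
            pool = [g for g in universe if g not in members]
            rng.shuffle(pool)
        members |= set(pool[:need])
        sets[name] = members
    return GeneSetDB(
        sets=sets,
        namespace={name: Namespace.pathway for name in sets},
        universe=set(universe),
    )


def generate_interaction_db(config: SyntheticConfig, truth: SyntheticTruth) -> list[TypedEdge]:
    """Planted typed edges plus Erdős–Rényi background at ``edge_density``.

    No self-loops; within a relation class each unordered pair appears
    once.  Background edges draw their class uniformly from the database
    classes (ECrel, PPrel, GErel) plus experimental PPI.
    """
    rng = _streams(config)[3]
    edges: dict[tuple[str, str, RelationClass], TypedEdge] = {}
    for s, cls, t in truth.edge_list:
        cls = RelationClass(cls)
        e = TypedEdge(s, t, cls, DEFAULT_PROVENANCE[cls])
        edges.setdefault((*e.pair, cls), e)
    background_classes = [RelationClass.ECrel, RelationClass.PPrel,
                          RelationClass.GErel, RelationClass.PPI]
    genes = list(config.gene_universe)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.random() < config.edge_density:
                cls = background_classes[int(rng.integers(len(background_classes)))]
                e = TypedEdge(genes[i], genes[j], cls, DEFAULT_PROVENANCE[cls])
                edges.setdefault((*e.pair, cls), e)
    return sorted(edges.values(), key=lambda e: (e.pair, e.relation_class.value))


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The package's default study conditions with a chosen seed."""
    return SyntheticConfig(seed=seed, **overrides)
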