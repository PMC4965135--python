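"""Pipeline configuration and end-to-end orchestration.

Stages run in order: mine -> associate -> consensus -> enrich ->
network -> integrate.  Every stage writes its table under the output
directory with a provenance header; identical configuration and inputs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, integration, network
from .association import Correction, association_table
from .consensus import ConsensusParams, consensus_table, consensus_targets
from .enrichment import enrich_pathways, enrichment_frame
from .io import (
    ParseError,
    read_corpus_jsonl,
    read_edges_tsv,
    read_gmt,
    read_predictions_tsv,
    write_cooccurrence_tsv,
    write_edges_tsv,
    write_stage_table,
)
from .network import build_graph, connectivity, hub_table, literature_edges
from .textmining import GeneLexicon, mine_corpus

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters for a full run."""

    corpus: str
    lexicon: str
    predictions: str
    pathways_gmt: str
    edges: str
    out_dir: str
    go_gmt: str | None = None
    disease_terms: tuple[str, ...] = ()
    alpha_association: float = 0.01
    alpha_pathway: float = 0.05
    alpha_literature: float = 0.01
    min_votes: int = 4
    correction: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_association", "alpha_pathway", "alpha_literature"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        Correction(self.correction)
        self.disease_terms = tuple(self.disease_terms)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def validate_paths(self) -> None:
        for name in ("corpus", "lexicon", "predictions", "pathways_gmt", "edges"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"configured {name} path does not exist: {p}")
        if self.go_gmt is not None and not Path(self.go_gmt).exists():
            raise FileNotFoundError(f"configured go_gmt path does not exist: {self.go_gmt}")


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return run
    return wrap


def run_pipeline(config: PipelineConfig) -> integration.OverlapReport:
    """Execute the full signature pipeline and write all stage artifacts."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()

    log.info("stage mine: tagging corpus")
    lexicon = _stage("mine")(GeneLexicon.from_tsv)(config.lexicon)
    articles = _stage("mine")(read_corpus_jsonl)(config.corpus)
    table = _stage("mine")(mine_corpus)(articles, lexicon, config.disease_terms)
    write_cooccurrence_tsv(
        table, out / "cooccurrence.tsv",
        header_lines=[f"stage=mine", f"config={digest}"],
    )

    log.info("stage associate: screening %d genes (N=%d, n=%d)", len(table.counts), table.N, table.n)
    assoc = _stage("associate")(association_table)(
        table, correction=config.correction, alpha=config.alpha_association
    )
    write_stage_table(assoc, out / "association.tsv", "associate", digest)
    disease_genes = sorted(assoc.loc[assoc["significant"], "gene"])
    disease_p = dict(zip(assoc["gene"], assoc["p"]))

    log.info("stage consensus: voting")
    matrix = _stage("consensus")(read_predictions_tsv)(config.predictions)
    params = ConsensusParams(min_votes=config.min_votes)
    targets = _stage("consensus")(consensus_targets)(matrix, params)
    votes = dict(matrix.vote_counts())
    write_stage_table(consensus_table(matrix, params), out / "consensus.tsv", "consensus", digest)

    log.info("stage enrich: pathway over-representation on %d targets", len(targets))
    pathway_db = _stage("enrich")(read_gmt)(config.pathways_gmt)
    pathway_records = _stage("enrich")(enrich_pathways)(targets, pathway_db, config.alpha_pathway)
    write_stage_table(enrichment_frame(pathway_records), out / "pathway_enrichment.tsv", "enrich", digest)
    significant = [r.name for r in pathway_records if r.significant]

    if config.go_gmt is not None:
        from .enrichment import classify_go
        go_db = _stage("enrich")(read_gmt)(config.go_gmt, namespace="biological_process")
        go_records = _stage("enrich")(classify_go)(targets, go_db)
        write_stage_table(enrichment_frame(go_records), out / "go_classification.tsv", "enrich", digest)

    log.info("stage network: building typed interaction graph")
    db_edges = _stage("network")(read_edges_tsv)(config.edges)
    lit_edges = _stage("network")(literature_edges)(table, alpha=config.alpha_literature)
    graph = _stage("network")(build_graph)([db_edges, lit_edges])
    write_edges_tsv(graph.edges, out / "network_edges.tsv",
                    header_lines=[f"stage=network", f"config={digest}"])
    conn = connectivity(graph)
    write_stage_table(
        pd.DataFrame(conn, columns=["gene", "degree"]), out / "connectivity.tsv", "network", digest
    )
    write_stage_table(hub_table(graph), out / "hubs.tsv", "network", digest)

    log.info("stage integrate: overlap signature")
    overlap = integration.intersect_sets(disease_genes, targets)
    provenance = {
        g: {"disease_p": disease_p.get(g), "n_votes": int(votes.get(g, 0))} for g in overlap
    }
    report = _stage("integrate")(integration.overlap_network)(
        overlap, graph, pathway_db.subset(significant), provenance
    )
    write_stage_table(report.to_frame(), out / "overlap.tsv", "integrate", digest)
    if report.subgraph is not None:
        write_edges_tsv(report.subgraph.edges, out / "overlap_edges.tsv",
                        header_lines=[f"stage=integrate", f"config={digest}"])
    return report
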