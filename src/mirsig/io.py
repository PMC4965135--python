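"""Readers and writers for the pipeline's on-disk formats.

Corpus: JSONL, one object per article (id, text, optional disease flag).
Lexicon: TSV (canonical_symbol, synonyms pipe-separated).
Predictions: TSV, either gene x tool 0/1 or long (gene, tool).
Gene sets: GMT (name, description, tab-separated members).
Edges: SIF-like TSV (source, relation_class, target, provenance).
Count tables: TSV with '# key=value' header metadata.

All tabular output is TSV with '.' decimals; every table written by a
pipeline stage carries a comment header naming the stage, the package
version, and the configuration digest, so reruns diff cleanly.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import CooccurrenceTable
from .consensus import PredictionMatrix, load_predictions
from .enrichment import GeneSetDB, Namespace
from .network import Provenance, RelationClass, TypedEdge
from .textmining import ArticleRecord

log = logging.getLogger(__name__)

__all__ = [
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "read_gmt",
    "write_gmt",
    "read_edges_tsv",
    "write_edges_tsv",
    "read_predictions_tsv",
    "write_predictions_tsv",
    "read_cooccurrence_tsv",
    "write_cooccurrence_tsv",
    "write_stage_table",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def read_corpus_jsonl(path) -> list[ArticleRecord]:
    articles = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
            if "id" not in obj or "text" not in obj:
                raise ParseError(f"{path}:{lineno}: article object needs 'id' and 'text'")
            articles.append(
                ArticleRecord(
                    id=str(obj["id"]),
                    text=str(obj["text"]),
                    disease_flag=obj.get("disease_flag"),
                )
            )
    return articles


def write_corpus_jsonl(articles: Iterable[ArticleRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in articles:
            obj = {"id": a.id, "text": a.text}
            if a.disease_flag is not None:
                obj["disease_flag"] = bool(a.disease_flag)
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_gmt(path, namespace: Namespace | str = Namespace.pathway,
             namespace_map: dict[str, str] | None = None) -> GeneSetDB:
    """Parse a GMT file into a GeneSetDB.

    Each row is ``name<TAB>description<TAB>member...``; duplicate set
    names are rejected, duplicate members within a set de-duplicated
    with a warning.  ``namespace_map`` (set name -> namespace) overrides
    the default namespace for individual sets.
    """
    sets: dict[str, set[str]] = {}
    ns: dict[str, Namespace] = {}
    default_ns = Namespace(namespace)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT row needs >= 3 tab-separated fields")
            name, _desc, *members = fields
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            unique = set(members)
            if len(unique) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} de-duplicated")
            sets[name] = unique
            ns[name] = Namespace(namespace_map[name]) if namespace_map and name in namespace_map else default_ns
    return GeneSetDB(sets=sets, namespace=ns)


def write_gmt(db: GeneSetDB, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(db.sets):
            members = "\t".join(sorted(db.sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_namespace_map_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return dict(zip(df["set_name"], df["namespace"]))


def read_edges_tsv(path) -> list[TypedEdge]:
    """Load SIF-like typed edges; malformed rows are reported and skipped."""
    edges: list[TypedEdge] = []
    bad = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["source", "relation_class", "target", "provenance"]
        if [h.strip("# ") for h in header[:4]] != expected:
            raise ParseError(f"{path}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                s, cls, t, prov = fields[:4]
                edges.append(TypedEdge(s, t, RelationClass(cls), Provenance(prov)))
            except (ValueError, IndexError) as exc:
                bad += 1
                log.error("%s:%d: bad edge row (%s); skipped", path, lineno, exc)
    if bad:
        log.warning("%s: skipped %d malformed edge row(s)", path, bad)
    return edges


def write_edges_tsv(edges: Iterable[TypedEdge], path, header_lines: Sequence[str] = ()) -> None:
    rows = sorted((e.source, e.relation_class.value, e.target, e.provenance.value) for e in edges)
    with open(path, "w", encoding="utf-8") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        fh.write("source\trelation_class\ttarget\tprovenance\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def read_predictions_tsv(path) -> PredictionMatrix:
    """Load a prediction table: wide gene x tool 0/1, or long (gene, tool)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns[:2]) == ["gene", "tool"]:
        per_tool: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            per_tool.setdefault(row["tool"], set()).add(row["gene"])
        return load_predictions(per_tool)
    if df.columns[0] != "gene":
        raise ParseError(f"{path}: first column must be 'gene'")
    tools = list(df.columns[1:])
    per_tool = {
        t: set(df.loc[df[t].astype(int) > 0, "gene"]) for t in tools
    }
    return load_predictions(per_tool)


def write_predictions_tsv(matrix: PredictionMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene"
    frame.to_csv(path, sep="\t")


def read_cooccurrence_tsv(path) -> CooccurrenceTable:
    meta: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line.strip("#\n ").partition("=")
            if key.strip() in ("N", "n"):
                meta[key.strip()] = int(value)
    if "N" not in meta or "n" not in meta:
        raise ParseError(f"{path}: missing '# N=' / '# n=' header metadata")
    counts = pd.read_csv(path, sep="\t", comment="#")
    return CooccurrenceTable(N=meta["N"], n=meta["n"], counts=counts)


def write_cooccurrence_tsv(table: CooccurrenceTable, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h in header_lines:
            fh.write(f"# {h}\n")
        fh.write(f"# N={table.N}\n# n={table.n}\n")
        table.counts.to_csv(fh, sep="\t", index=False)


def write_stage_table(df: pd.DataFrame, path, stage: str, config_digest: str) -> None:
    """Write a stage output table with the standard provenance header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# stage={stage}\n# version={__version__}\n# config={config_digest}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
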