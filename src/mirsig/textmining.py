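"""Dictionary-based gene mention tagging and corpus mining.

Gene mentions are found by case-insensitive, token-boundary-anchored
lexicon matching with a longest-match-first rule, followed by expansion
of slash conjunctions ("Caspase3/7" names both Caspase3 and Caspase7)
and normalization of every matched synonym to its canonical symbol.
Mentions are counted as document frequency: an article either mentions a
gene or it does not, so the hypergeometric co-citation model can treat
articles as sampling units.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .association import CooccurrenceTable

__all__ = [
    "GeneLexicon",
    "ArticleRecord",
    "resolve_conjunctions",
    "tag_mentions",
    "mine_corpus",
]

# shared-stem slash list: alphabetic-ending stem, numeric suffix, one or
# more further /numeric suffixes ("MAPK1/3", "Caspase3/7", "HG1/4/9")
_CONJUNCTION = re.compile(r"^([A-Za-z][A-Za-z0-9]*?[A-Za-z])(\d+)((?:/\d+)+)$")
_TOKEN = re.compile(r"[A-Za-z0-9][A-Za-z0-9/\-]*")


class LexiconCollisionError(ValueError):
    """A synonym maps to more than one canonical symbol."""


@dataclass
class GeneLexicon:
    """Mapping from canonical gene symbols to synonym sets.

    Every canonical symbol is a synonym of itself.  Matching is
    case-insensitive, so a synonym that differs from another only by case
    collides at load time.
    """

    entries: dict[str, set[str]]
    _canonical_of: dict[str, str] = field(init=False, repr=False)
    _pattern: re.Pattern = field(init=False, repr=False)

    def __post_init__(self) -> None:
        canonical_of: dict[str, str] = {}
        entries: dict[str, set[str]] = {}
        for canonical, synonyms in self.entries.items():
            syns = set(synonyms) | {canonical}
            for s in syns:
                key = s.lower()
                owner = canonical_of.get(key)
                if owner is not None and owner != canonical:
                    raise LexiconCollisionError(
                        f"synonym {s!r} maps to both {owner!r} and {canonical!r}"
                    )
                canonical_of[key] = canonical
            entries[canonical] = syns
        self.entries = entries
        self._canonical_of = canonical_of
        # longest-first alternation => a synonym that is a prefix of a longer
        # synonym at the same position never fires
        alternatives = sorted(canonical_of, key=len, reverse=True)
        body = "|".join(re.escape(a) for a in alternatives) or r"(?!x)x"
        self._pattern = re.compile(
            rf"(?<![A-Za-z0-9])(?:{body})(?![A-Za-z0-9])", re.IGNORECASE
        )

    @property
    def canonical_symbols(self) -> list[str]:
        return sorted(self.entries)

    def canonical(self, name: str) -> str | None:
        """Canonical symbol for a raw name, or None if unknown."""
        return self._canonical_of.get(name.lower())

    @classmethod
    def from_tsv(cls, path) -> "GeneLexicon":
        """Load a lexicon from TSV columns canonical_symbol, synonyms (pipe-separated)."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
        if "canonical_symbol" not in df.columns:
            raise ValueError("lexicon TSV needs a canonical_symbol column")
        entries: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            canonical = row["canonical_symbol"].strip()
            if canonical in entries:
                raise LexiconCollisionError(f"duplicate canonical symbol {canonical!r}")
            syns = {s.strip() for s in str(row.get("synonyms", "")).split("|") if s.strip()}
            entries[canonical] = syns
        return cls(entries)

    def to_tsv(self, path) -> None:
        rows = [
            {"canonical_symbol": c, "synonyms": "|".join(sorted(self.entries[c]))}
            for c in self.canonical_symbols
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ArticleRecord:
    """One mined document: id, title+abstract text, and derived fields."""

    id: str
    text: str
    disease_flag: bool | None = None
    mentions: set[str] = field(default_factory=set)


def resolve_conjunctions(raw_token: str) -> set[str]:
    """Expand a shared-stem slash token into its member names.

    "Caspase3/7" -> {"Caspase3", "Caspase7"}; tokens without the pattern
    pass through unchanged as singletons.
    """
    if not raw_token:
        raise ValueError("empty token")
    m = _CONJUNCTION.match(raw_token)
    if m is None:
        return {raw_token}
    stem, first, rest = m.groups()
    suffixes = [first] + rest.strip("/").split("/")
    return {stem + s for s in suffixes}


def tag_mentions(text: str, lexicon: GeneLexicon) -> set[str]:
    """Canonical symbols mentioned in ``text``.

    Two passes: direct lexicon matching (longest-first, token-boundary
    anchored, case-insensitive) and conjunction expansion of slash tokens
    whose expanded names are in the lexicon.
    """
    found: set[str] = set()
    for match in lexicon._pattern.finditer(text):
        canonical = lexicon.canonical(match.group(0))
        if canonical is not None:
            found.add(canonical)
    for token in _TOKEN.findall(text):
        if "/" not in token:
            continue
        for name in resolve_conjunctions(token):
            canonical = lexicon.canonical(name)
            if canonical is not None:
                found.add(canonical)
    return found


def _matches_any_term(text: str, term_patterns: Sequence[re.Pattern]) -> bool:
    return any(p.search(text) for p in term_patterns)


def mine_corpus(
    articles: Iterable[ArticleRecord],
    lexicon: GeneLexicon,
    disease_terms: Iterable[str] = (),
) -> CooccurrenceTable:
    """Tag every article and assemble the per-gene co-occurrence table.

    An article is disease-relevant when it carries ``disease_flag=True``
    or its text matches any configured disease term.  The table covers
    every canonical symbol in the lexicon, including never-mentioned
    genes (m = 0).
    """
    if not lexicon.entries:
        raise ValueError("empty lexicon")
    term_patterns = [
        re.compile(rf"(?<![A-Za-z0-9]){re.escape(t)}(?![A-Za-z0-9])", re.IGNORECASE)
        for t in disease_terms
    ]
    genes = lexicon.canonical_symbols
    m = {g: 0 for g in genes}
    k = {g: 0 for g in genes}
    N = 0
    n = 0
    article_mentions: list[tuple[set[str], bool]] = []
    for article in articles:
        N += 1
        mentions = tag_mentions(article.text, lexicon)
        article.mentions = mentions
        disease = bool(article.disease_flag) or _matches_any_term(article.text, term_patterns)
        if disease:
            n += 1
        for g in mentions:
            m[g] += 1
            if disease:
                k[g] += 1
        article_mentions.append((mentions, disease))
    if N == 0:
        raise ValueError("empty corpus")
    counts = pd.DataFrame({"gene": genes, "m": [m[g] for g in genes], "k": [k[g] for g in genes]})
    return CooccurrenceTable(N=N, n=n, counts=counts, article_mentions=article_mentions)
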