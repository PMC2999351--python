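"""Multi-pattern concept tagging of documents with exact character locations.

The matcher scans title and abstract independently.  Candidate windows run
over content (non-stopword) tokens; stopwords inside a window are skipped
for lookup but the reported character span covers the full original window,
so "nucleus of the solitary tract" is hit by the pattern
(nucleus, solitary, tract) with a span covering all five words.  A match
never crosses a sentence boundary.  Under the best-match policy, a shorter
span fully contained in an emitted longer span is suppressed; overlapping
but non-nested spans are both kept.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from .lexicon import Lexicon
from .text import segment_sentences, tokenize

FIELDS = ("title", "abstract")


@dataclass(frozen=True)
class Document:
    """A Medline-like record: identifier, title, abstract, MeSH headings."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    mesh_terms: Tuple[str, ...] = ()

    def field_text(self, name: str) -> str:
        if name not in FIELDS:
            raise ValueError(f"unknown field {name!r}")
        return getattr(self, name)


@dataclass(frozen=True, order=True)
class Match:
    """A located concept mention: which field, which characters, which sentence."""

    doc_id: str
    concept_id: str
    field: str
    char_start: int
    char_end: int
    matched_text: str
    sentence_index: int


@dataclass(frozen=True, order=True)
class CooccurrencePair:
    concept_a: str
    concept_b: str
    level: str
    doc_id: str
    count: int


def _sentence_index_of(starts: Sequence[int], pos: int) -> int:
    # starts is the sorted list of sentence span starts; tokens always fall
    # inside some span because spans cover all non-whitespace characters.
    return max(bisect_right(starts, pos) - 1, 0)


def find_matches(
    doc: Document,
    lexicon: Lexicon,
    suppress_contained: bool = True,
) -> List[Match]:
    """Locate every lexicon pattern in the document's title and abstract.

    With ``suppress_contained=False`` all raw candidate matches are returned
    (useful for auditing against a naive scan); the default applies the
    best-match policy described in the module docstring.
    """
    max_len = lexicon.max_pattern_tokens
    if max_len == 0:
        return []
    out: List[Match] = []
    for fname in FIELDS:
        text = doc.field_text(fname)
        if not text:
            continue
        tokens = tokenize(text)
        if not tokens:
            continue
        sent_starts = [s for s, _ in segment_sentences(text)]
        folded = [t.lower() for t, _, _ in tokens]
        sent_of = [_sentence_index_of(sent_starts, s) for _, s, _ in tokens]
        content = [i for i, t in enumerate(folded) if t not in lexicon.stopwords]
        candidates: List[Match] = []
        for a in range(len(content)):
            first = content[a]
            for L in range(1, max_len + 1):
                if a + L > len(content):
                    break
                last = content[a + L - 1]
                if sent_of[last] != sent_of[first]:
                    break  # windows only grow; further L also cross
                key = tuple(folded[content[a + j]] for j in range(L))
                cids = lexicon.patterns.get(key)
                if not cids:
                    continue
                start, end = tokens[first][1], tokens[last][2]
                for cid in sorted(cids):
                    candidates.append(
                        Match(doc.doc_id, cid, fname, start, end,
                              text[start:end], sent_of[first])
                    )
        if suppress_contained:
            candidates = _suppress_contained(candidates)
        out.extend(candidates)
    out.sort()
    return out


def _suppress_contained(candidates: List[Match]) -> List[Match]:
    spans = {(m.char_start, m.char_end) for m in candidates}
    kept = []
    for m in candidates:
        contained = any(
            (s <= m.char_start and m.char_end <= e)
            and (s, e) != (m.char_start, m.char_end)
            for s, e in spans
        )
        if not contained:
            kept.append(m)
    return kept


def mesh_map(doc: Document, mesh_to_concept: Mapping[str, str]) -> List[str]:
    """Concepts linked through exact case-insensitive MeSH heading lookup.

    These links carry no character location; they exist only at record level.
    """
    table = {k.lower(): v for k, v in mesh_to_concept.items()}
    out: List[str] = []
    for mh in doc.mesh_terms:
        cid = table.get(mh.strip().lower())
        if cid is not None and cid not in out:
            out.append(cid)
    return out


def link_documents(
    corpus: Iterable[Document],
    lexicon: Lexicon,
    mesh_to_concept: Mapping[str, str] | None = None,
) -> Dict[str, Set[str]]:
    """concept_id -> set of doc_ids linked by text match OR MeSH heading."""
    mesh_to_concept = mesh_to_concept or {}
    links: Dict[str, Set[str]] = {}
    for doc in corpus:
        hit = {m.concept_id for m in find_matches(doc, lexicon)}
        hit.update(mesh_map(doc, mesh_to_concept))
        for cid in hit:
            links.setdefault(cid, set()).add(doc.doc_id)
    return links


def cooccurrence(
    matches: Iterable[Match],
    mesh_links: Mapping[str, Iterable[str]] | None = None,
    level: str = "abstract",
) -> List[CooccurrencePair]:
    """Concept pairs co-mentioned in the same sentence or the same record.

    At abstract level a pair counts once per document where both concepts
    occur (text match in either field, or a MeSH link — MeSH links have no
    sentence position and so participate only here).  At sentence level a
    pair counts once per (document, field, sentence) unit with text matches
    for both; the per-document count is the number of such units.
    """
    if level not in ("sentence", "abstract"):
        raise ValueError(f"level must be 'sentence' or 'abstract', got {level!r}")
    mesh_links = mesh_links or {}
    counts: Dict[Tuple[str, str, str], int] = {}

    def _add(unit_concepts: Iterable[str], doc_id: str) -> None:
        cs = sorted(set(unit_concepts))
        for i, a in enumerate(cs):
            for b in cs[i + 1:]:
                counts[(a, b, doc_id)] = counts.get((a, b, doc_id), 0) + 1

    if level == "abstract":
        per_doc: Dict[str, Set[str]] = {}
        for m in matches:
            per_doc.setdefault(m.doc_id, set()).add(m.concept_id)
        for doc_id, cids in mesh_links.items():
            per_doc.setdefault(doc_id, set()).update(cids)
        for doc_id, cs in per_doc.items():
            _add(cs, doc_id)
    else:
        per_unit: Dict[Tuple[str, str, int], Set[str]] = {}
        for m in matches:
            per_unit.setdefault((m.doc_id, m.field, m.sentence_index), set()).add(
                m.concept_id
            )
        for (doc_id, _f, _s), cs in per_unit.items():
            _add(cs, doc_id)

    return sorted(
        CooccurrencePair(a, b, level, doc_id, c)
        for (a, b, doc_id), c in counts.items()
    )
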