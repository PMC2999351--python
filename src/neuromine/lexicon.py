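"""Compile multi-source anatomical term tables into a matchable lexicon.

Brain-structure nomenclatures disagree across atlases, so raw term rows are
first unified to canonical concept ids, then filtered (abbreviations out,
short strings out), then each surviving term is expanded into the set of
normalized token-sequence patterns the matcher will look up: case-folded,
stopword-stripped, with regular singular/plural variants per token and all
word-order permutations of the content tokens (capped to bound the
factorial blowup).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

from .text import DEFAULT_STOPWORDS, token_variants, tokenize

Pattern = Tuple[str, ...]

DEFAULT_MIN_LENGTH = 5
DEFAULT_MAX_PERMUTE = 4


class MappingError(KeyError):
    """A (term, source) pair has no entry in the concept map under strict policy."""


class VariantError(ValueError):
    """A term reduced to zero content tokens after stopword removal."""


@dataclass(frozen=True)
class TermEntry:
    """One vocabulary row: a surface string tied to a concept in one source."""

    term: str
    concept_id: str
    source: str
    is_abbreviation: bool = False

    def __post_init__(self):
        if not self.term.strip():
            raise ValueError("term must be non-empty after trimming")


@dataclass
class Lexicon:
    """Compiled pattern index: normalized token sequence -> concept ids."""

    patterns: Dict[Pattern, Set[str]] = field(default_factory=dict)
    stopwords: FrozenSet[str] = DEFAULT_STOPWORDS
    min_length: int = DEFAULT_MIN_LENGTH
    max_permute_tokens: int = DEFAULT_MAX_PERMUTE
    provenance: Dict[Pattern, List[TermEntry]] = field(default_factory=dict)

    @property
    def max_pattern_tokens(self) -> int:
        return max((len(p) for p in self.patterns), default=0)

    def concepts(self) -> Set[str]:
        out: Set[str] = set()
        for cids in self.patterns.values():
            out |= cids
        return out


def unify_terms(
    entries: Iterable[TermEntry],
    concept_map: Dict[Tuple[str, str], str] | None = None,
    strict: bool = False,
) -> List[TermEntry]:
    """Map per-atlas concept ids to canonical ids and collapse duplicates.

    ``concept_map`` keys are (term, source) pairs; entries without a mapping
    keep their own concept id (pass-through) unless ``strict`` is set, in
    which case an unmapped pair raises :class:`MappingError`.  Duplicate
    (term, concept_id) rows after mapping are collapsed to the first one.
    """
    concept_map = concept_map or {}
    seen: Set[Tuple[str, str]] = set()
    out: List[TermEntry] = []
    for e in entries:
        key = (e.term, e.source)
        if key in concept_map:
            cid = concept_map[key]
        elif strict:
            raise MappingError(f"no canonical concept for {key!r}")
        else:
            cid = e.concept_id
        dedup = (e.term, cid)
        if dedup in seen:
            continue
        seen.add(dedup)
        out.append(TermEntry(e.term, cid, e.source, e.is_abbreviation))
    return out


def term_length(term: str) -> int:
    """Character length of a term counting all non-whitespace characters."""
    return sum(1 for c in term if not c.isspace())


def filter_terms(
    entries: Iterable[TermEntry],
    min_length: int = DEFAULT_MIN_LENGTH,
    exclude_abbreviations: bool = True,
) -> List[TermEntry]:
    """Drop abbreviations and terms shorter than ``min_length`` characters.

    Both filters reduce false positives: short strings and abbreviations
    ("CA1") are highly ambiguous in running text.  Order is preserved.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    return [
        e
        for e in entries
        if term_length(e.term) >= min_length
        and not (exclude_abbreviations and e.is_abbreviation)
    ]


def generate_variants(
    term: str,
    stopwords: FrozenSet[str] = DEFAULT_STOPWORDS,
    max_permute_tokens: int = DEFAULT_MAX_PERMUTE,
) -> Set[Pattern]:
    """All normalized patterns a term can surface as.

    The term is tokenized and case-folded, stopword tokens are removed, each
    remaining content token is expanded to its inflectional variants, and
    every ordering of the content tokens is emitted when there are at most
    ``max_permute_tokens`` of them (otherwise only the original order).
    """
    tokens = [t.lower() for t, _, _ in tokenize(term)]
    content = [t for t in tokens if t not in stopwords]
    if not content:
        raise VariantError(f"term {term!r} has no content tokens after stopword removal")
    variant_sets = [sorted(token_variants(t)) for t in content]
    patterns: Set[Pattern] = set()
    for combo in itertools.product(*variant_sets):
        if len(content) <= max_permute_tokens:
            patterns.update(itertools.permutations(combo))
        else:
            patterns.add(tuple(combo))
    return patterns


def build_lexicon(
    entries: Sequence[TermEntry],
    stopwords: FrozenSet[str] = DEFAULT_STOPWORDS,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_permute_tokens: int = DEFAULT_MAX_PERMUTE,
) -> Lexicon:
    """Compile unified entries into a :class:`Lexicon`.

    The length/abbreviation filter is re-applied so the lexicon invariants
    hold regardless of caller discipline.  A pattern produced by terms of two
    different concepts maps to both concept ids.
    """
    stopwords = frozenset(w.lower() for w in stopwords)
    retained = filter_terms(entries, min_length=min_length)
    lex = Lexicon(
        stopwords=stopwords,
        min_length=min_length,
        max_permute_tokens=max_permute_tokens,
    )
    if not retained:
        warnings.warn("no terms retained; returning an empty lexicon", stacklevel=2)
        return lex
    for e in retained:
        for pat in generate_variants(e.term, stopwords, max_permute_tokens):
            lex.patterns.setdefault(pat, set()).add(e.concept_id)
            lex.provenance.setdefault(pat, []).append(e)
    return lex
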