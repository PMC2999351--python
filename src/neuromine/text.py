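"""Tokenization, sentence segmentation and the inflection rule set.

These primitives are shared by the lexicon builder and the matcher so that a
term normalized at dictionary-compile time and a text window normalized at
match time go through byte-identical code paths.
"""

from __future__ import annotations

import re
from typing import List, Tuple

# A token is a maximal run of letters, digits and apostrophes.  Hyphens and
# all other punctuation separate tokens, which gives hyphen/space equivalence
# for free ("locus-coeruleus" and "locus coeruleus" tokenize identically).
_TOKEN_RE = re.compile(r"[A-Za-z0-9']+")

_SENT_TERMINATORS = frozenset(".!?")

#: Default high-frequency function words stripped from patterns and skipped
#: inside candidate windows at match time.  Configurable everywhere it is used.
DEFAULT_STOPWORDS = frozenset(
    {"the", "of", "a", "an", "in", "on", "and", "or"}
)

# Word endings after which the regular plural takes -es rather than -s.
_ES_ENDINGS = ("s", "x", "z", "ch", "sh")
# Endings never stripped by the singular rule: -ss ("glass"), and the Latin
# -us/-is endings ("nucleus", "neuraxis") whose plural is irregular anyway.
_NO_STRIP_ENDINGS = ("ss", "us", "is")

_VOWELS = "aeiou"


def tokenize(text: str) -> List[Tuple[str, int, int]]:
    """Split *text* into (token, char_start, char_end) triples.

    Offsets are 0-based, half-open, in code points into the original string,
    so ``text[start:end] == token`` for every emitted triple.
    """
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def segment_sentences(text: str) -> List[Tuple[int, int]]:
    """Return ordered, disjoint sentence spans covering all non-whitespace.

    A sentence break occurs at ``.``, ``!`` or ``?`` followed by whitespace
    and then an uppercase letter or the end of the text.  This deliberately
    leaves "E. coli grows." as a single sentence.
    """
    breaks = []
    n = len(text)
    for i, ch in enumerate(text):
        if ch not in _SENT_TERMINATORS:
            continue
        j = i + 1
        if j >= n or not text[j].isspace():
            continue
        while j < n and text[j].isspace():
            j += 1
        if j == n or text[j].isupper():
            breaks.append(i + 1)
    spans = []
    start = 0
    for b in breaks + [n]:
        s, e = start, b
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            spans.append((s, e))
        start = b
    return spans


def pluralize(token: str) -> str | None:
    """Regular English plural of a lowercase token, or None when the rule
    does not apply (possessives and tokens containing digits are left alone).
    """
    if "'" in token or any(c.isdigit() for c in token) or len(token) < 2:
        return None
    if token.endswith("y") and token[-2] not in _VOWELS:
        return token[:-1] + "ies"
    if token.endswith(_ES_ENDINGS):
        return token + "es"
    return token + "s"


def singularize(token: str) -> str | None:
    """Inverse of :func:`pluralize` where unambiguous, else None."""
    if "'" in token or any(c.isdigit() for c in token):
        return None
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("es") and token[:-2].endswith(_ES_ENDINGS):
        return token[:-2]
    if token.endswith("s") and not token.endswith(_NO_STRIP_ENDINGS) and len(token) > 2:
        return token[:-1]
    return None


def token_variants(token: str) -> frozenset:
    """The inflectional variant set of one lowercase token: itself plus its
    regular plural and/or singular form where the rules apply."""
    out = {token}
    for f in (pluralize, singularize):
        v = f(token)
        if v:
            out.add(v)
    return frozenset(out)
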