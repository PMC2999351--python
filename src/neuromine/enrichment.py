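"""Rank concepts in a foreground document set against corpus background.

The device is deliberately simple: a concept seen in k of n foreground
documents and K of N corpus documents gets a fold ratio (k/n)/(K/N) and a
hypergeometric upper-tail p-value P(X >= k) for drawing n documents without
replacement from a corpus of N containing K marked ones.  Counting is
document-level: a concept counts once per document no matter how often it is
mentioned.  Benjamini-Hochberg adjustment is optional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Set

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

METHODS = ("fold", "hypergeometric")
ADJUSTMENTS = ("none", "benjamini_hochberg")


@dataclass
class BackgroundFreq:
    """Corpus-wide document frequency of each concept."""

    doc_count: Dict[str, int]
    total_docs: int

    def __post_init__(self):
        for cid, c in self.doc_count.items():
            if not 0 < c <= self.total_docs:
                raise ValueError(
                    f"concept {cid!r}: doc_count {c} outside (0, {self.total_docs}]"
                )


@dataclass(frozen=True)
class EnrichmentRow:
    concept_id: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    p_value: float
    q_value: float


def compute_background(
    concept_links: Mapping[str, Set[str]], total_docs: int
) -> BackgroundFreq:
    """Document frequency per concept from concept -> doc-id link sets."""
    counts = {cid: len(docs) for cid, docs in concept_links.items() if docs}
    too_big = [cid for cid, c in counts.items() if c > total_docs]
    if too_big:
        raise ValueError(
            f"total_docs={total_docs} smaller than link set of {too_big[0]!r}"
        )
    return BackgroundFreq(counts, total_docs)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); exact log-space tail."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def rank_concepts(
    foreground: Set[str],
    concept_links: Mapping[str, Set[str]],
    background: BackgroundFreq,
    method: str = "hypergeometric",
    adjust: str = "none",
) -> List[EnrichmentRow]:
    """Every concept present in the foreground, scored and sorted.

    Sorting is by fold descending for ``method='fold'`` and p-value
    ascending for ``method='hypergeometric'``; ties break on concept id.
    Concepts missing from the background (possible with a user-supplied
    background) get K floored to k, with a warning.
    """
    if not foreground:
        raise ValueError("foreground document set is empty")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if adjust not in ADJUSTMENTS:
        raise ValueError(f"adjust must be one of {ADJUSTMENTS}, got {adjust!r}")
    n = len(foreground)
    N = background.total_docs
    if n > N:
        raise ValueError(f"foreground size {n} exceeds corpus size {N}")

    rows = []
    for cid in sorted(concept_links):
        k = len(concept_links[cid] & foreground)
        if k == 0:
            continue
        K = background.doc_count.get(cid)
        if K is None:
            warnings.warn(
                f"concept {cid!r} absent from background; flooring K to k={k}",
                stacklevel=2,
            )
            K = k
        fold = (k / n) / (K / N)
        p = hypergeom_upper_tail(k, n, K, N)
        rows.append((cid, k, K, fold, p))

    if not rows:
        return []
    pvals = np.array([r[4] for r in rows])
    if adjust == "benjamini_hochberg":
        qvals = multipletests(pvals, method="fdr_bh")[1]
    else:
        qvals = pvals
    out = [
        EnrichmentRow(cid, k, n, K, N, fold, p, float(q))
        for (cid, k, K, fold, p), q in zip(rows, qvals)
    ]
    if method == "fold":
        out.sort(key=lambda r: (-r.fold, r.concept_id))
    else:
        out.sort(key=lambda r: (r.p_value, r.concept_id))
    return out
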