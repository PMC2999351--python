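"""Independent brute-force oracles used only by the test suite.

Each deliberately re-derives its answer from first principles (regex scans,
combinatorial sums, two-pass means) without calling the code paths it
checks.
"""

import math
import re

_TOK = re.compile(r"[A-Za-z0-9']+")
_TERM = re.compile(r"[.!?]")


def naive_sentence_spans(text):
    """Trace of the segmentation rule by direct character scan."""
    breaks = []
    for m in _TERM.finditer(text):
        j = m.end()
        if j < len(text) and text[j].isspace():
            while j < len(text) and text[j].isspace():
                j += 1
            if j == len(text) or text[j].isupper():
                breaks.append(m.end())
    spans, start = [], 0
    for b in breaks + [len(text)]:
        chunk = text[start:b]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if start + lead < b - trail:
            spans.append((start + lead, b - trail))
        start = b
    return spans


def naive_scan(doc, patterns, stopwords):
    """Every-window dictionary scan, pre-suppression.

    Tests each token window with non-stopword endpoints against every
    pattern after dropping stopword tokens; a window never crosses a
    sentence boundary.  Returns (field, start, end, concept) tuples.
    """
    hits = set()
    for field in ("title", "abstract"):
        text = getattr(doc, field)
        toks = [(m.group(0).lower(), m.start(), m.end())
                for m in _TOK.finditer(text)]
        spans = naive_sentence_spans(text)

        def sent_of(pos):
            for k, (s, e) in enumerate(spans):
                if s <= pos < e:
                    return k
            raise AssertionError("token outside all sentence spans")

        for i in range(len(toks)):
            if toks[i][0] in stopwords:
                continue
            for j in range(i, len(toks)):
                if toks[j][0] in stopwords:
                    continue
                if sent_of(toks[i][1]) != sent_of(toks[j][1]):
                    break
                window = tuple(t for t, _, _ in toks[i:j + 1]
                               if t not in stopwords)
                for pat, cids in patterns.items():
                    if window == pat:
                        for c in cids:
                            hits.add((field, toks[i][1], toks[j][2], c))
    return hits


def hypergeom_tail_sum(k, n, K, N):
    """P(X >= k) as an explicit sum of counting ratios."""
    if k <= 0:
        return 1.0
    total = math.comb(N, n)
    hi = min(n, K)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, hi + 1)) / total


def bh_stepup(pvals):
    """Benjamini-Hochberg step-up computed by the textbook recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, pvals[i] * m / rank_from_top)
        q[i] = prev
    return q


def two_pass_mean(values):
    total = 0.0
    count = 0
    for v in values:
        total += v
        count += 1
    return total / count


def pearson_sum_formula(xs, ys):
    """Textbook sum formula for Pearson's r."""
    n = len(xs)
    sx, sy = sum(xs), sum(ys)
    sxx = sum(x * x for x in xs)
    syy = sum(y * y for y in ys)
    sxy = sum(x * y for x, y in zip(xs, ys))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den
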