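"""Readers and writers for the plain-text exchange formats.

TSV dialect: tab-separated, UTF-8, ``#``-prefixed comment/header lines, no
quoting (tabs are forbidden in fields).  Corpora are JSONL with keys doc_id,
title, abstract, mesh_terms.  All writers go through an atomic
temp-file-and-rename so a crashed run never leaves a truncated output, and
every file starts with comment lines recording the tool version and the
parameters used.
"""

from __future__ import annotations

import json
import os
import tempfile
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np

from . import __version__
from .enrichment import BackgroundFreq, EnrichmentRow
from .lexicon import Lexicon, TermEntry
from .matcher import CooccurrencePair, Document, Match
from .voxel import ExpressionGrid, StructureMap, StructureScore


class FormatError(ValueError):
    """Malformed input file."""


def _check_field(value: str) -> str:
    if "\t" in value or "\n" in value:
        raise FormatError(f"tabs/newlines forbidden in TSV fields: {value!r}")
    return value


def atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(
    path: str,
    columns: Sequence[str],
    rows: Iterable[Sequence],
    params: Mapping[str, object] | None = None,
    extra_comments: Sequence[str] = (),
) -> None:
    lines = [f"# neuromine {__version__}"]
    if params:
        joined = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        lines.append(f"# params: {joined}")
    lines.extend(f"# {c}" for c in extra_comments)
    lines.append("\t".join(columns))
    for r in rows:
        lines.append("\t".join(_check_field(str(v)) for v in r))
    atomic_write(path, "\n".join(lines) + "\n")


def read_tsv(path: str) -> Tuple[List[str], List[List[str]], List[str]]:
    """Return (column names, data rows, comment lines without '#')."""
    comments: List[str] = []
    header: List[str] | None = None
    rows: List[List[str]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line[1:].strip())
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
            else:
                if len(parts) != len(header):
                    raise FormatError(
                        f"{path}: row has {len(parts)} fields, header has {len(header)}"
                    )
                rows.append(parts)
    if header is None:
        raise FormatError(f"{path}: no header line")
    return header, rows, comments


# -- term tables and lexicons ---------------------------------------------

def read_term_table(path: str) -> List[TermEntry]:
    header, rows, _ = read_tsv(path)
    want = ["term", "concept_id", "source", "is_abbreviation"]
    if header != want:
        raise FormatError(f"{path}: expected columns {want}, got {header}")
    return [TermEntry(t, c, s, a == "1") for t, c, s, a in rows]


def read_concept_map(path: str) -> Dict[Tuple[str, str], str]:
    header, rows, _ = read_tsv(path)
    want = ["term", "source", "canonical_concept_id"]
    if header != want:
        raise FormatError(f"{path}: expected columns {want}, got {header}")
    return {(t, s): c for t, s, c in rows}


def read_stopwords(path: str) -> frozenset:
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            w.strip().lower() for w in fh if w.strip() and not w.startswith("#")
        )


def write_lexicon(path: str, lex: Lexicon, params: Mapping[str, object] | None = None) -> None:
    rows = [
        (" ".join(pat), ",".join(sorted(cids)))
        for pat, cids in sorted(lex.patterns.items())
    ]
    extra = [
        f"stopwords: {','.join(sorted(lex.stopwords))}",
        f"min_length: {lex.min_length}",
        f"max_permute_tokens: {lex.max_permute_tokens}",
    ]
    write_tsv(path, ["pattern_tokens", "concept_ids"], rows, params, extra)


def read_lexicon(path: str) -> Lexicon:
    header, rows, comments = read_tsv(path)
    if header != ["pattern_tokens", "concept_ids"]:
        raise FormatError(f"{path}: not a lexicon file")
    stop, minlen, maxperm = Lexicon().stopwords, 5, 4
    for c in comments:
        if c.startswith("stopwords:"):
            stop = frozenset(w for w in c.split(":", 1)[1].strip().split(",") if w)
        elif c.startswith("min_length:"):
            minlen = int(c.split(":", 1)[1])
        elif c.startswith("max_permute_tokens:"):
            maxperm = int(c.split(":", 1)[1])
    lex = Lexicon(stopwords=stop, min_length=minlen, max_permute_tokens=maxperm)
    for pat_s, cids_s in rows:
        lex.patterns[tuple(pat_s.split(" "))] = set(cids_s.split(","))
    return lex


# -- corpora, matches, co-occurrence --------------------------------------

def write_corpus(path: str, docs: Iterable[Document]) -> None:
    lines = []
    for d in docs:
        lines.append(json.dumps(
            {"doc_id": d.doc_id, "title": d.title, "abstract": d.abstract,
             "mesh_terms": list(d.mesh_terms)},
            sort_keys=True,
        ))
    atomic_write(path, "\n".join(lines) + "\n")


def read_corpus(path: str) -> List[Document]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                docs.append(Document(obj["doc_id"], obj.get("title", ""),
                                     obj.get("abstract", ""),
                                     tuple(obj.get("mesh_terms", []))))
            except (json.JSONDecodeError, KeyError, TypeError) as e:
                raise FormatError(f"{path}:{i + 1}: bad corpus record: {e}") from e
    ids = [d.doc_id for d in docs]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate doc_ids")
    return docs


MATCH_COLUMNS = ["doc_id", "concept_id", "field", "char_start", "char_end",
                 "matched_text", "sentence_index"]


def write_matches(path: str, matches: Iterable[Match],
                  params: Mapping[str, object] | None = None) -> None:
    rows = [
        (m.doc_id, m.concept_id, m.field, m.char_start, m.char_end,
         m.matched_text, m.sentence_index)
        for m in matches
    ]
    write_tsv(path, MATCH_COLUMNS, rows, params)


def read_matches(path: str) -> List[Match]:
    header, rows, _ = read_tsv(path)
    if header != MATCH_COLUMNS:
        raise FormatError(f"{path}: not a match file")
    return [Match(d, c, f, int(s), int(e), t, int(si))
            for d, c, f, s, e, t, si in rows]


def read_mesh_table(path: str) -> Dict[str, str]:
    header, rows, _ = read_tsv(path)
    if header != ["mesh_term", "concept_id"]:
        raise FormatError(f"{path}: expected columns mesh_term, concept_id")
    return {m: c for m, c in rows}


def write_mesh_table(path: str, table: Mapping[str, str]) -> None:
    write_tsv(path, ["mesh_term", "concept_id"], sorted(table.items()))


def write_cooccurrence(path: str, pairs: Iterable[CooccurrencePair],
                       params: Mapping[str, object] | None = None) -> None:
    rows = [(p.concept_a, p.concept_b, p.level, p.doc_id, p.count) for p in pairs]
    write_tsv(path, ["concept_a", "concept_b", "level", "doc_id", "count"],
              rows, params)


def read_doc_concept_links(path: str) -> Dict[str, Set[str]]:
    """TSV doc_id\tconcept_id -> map doc_id -> concepts (for MeSH links)."""
    header, rows, _ = read_tsv(path)
    if header != ["doc_id", "concept_id"]:
        raise FormatError(f"{path}: expected columns doc_id, concept_id")
    out: Dict[str, Set[str]] = {}
    for d, c in rows:
        out.setdefault(d, set()).add(c)
    return out


# -- enrichment -------------------------------------------------------------

def write_background(path: str, bg: BackgroundFreq) -> None:
    write_tsv(path, ["concept_id", "doc_count"],
              sorted(bg.doc_count.items()),
              extra_comments=[f"total_docs={bg.total_docs}"])


def read_background(path: str) -> BackgroundFreq:
    header, rows, comments = read_tsv(path)
    if header != ["concept_id", "doc_count"]:
        raise FormatError(f"{path}: not a background file")
    total = None
    for c in comments:
        if c.startswith("total_docs="):
            total = int(c.split("=", 1)[1])
    if total is None:
        raise FormatError(f"{path}: missing '#total_docs=N' header")
    return BackgroundFreq({c: int(n) for c, n in rows}, total)


def read_concept_links(path: str) -> Dict[str, Set[str]]:
    header, rows, _ = read_tsv(path)
    if header != ["concept_id", "doc_id"]:
        raise FormatError(f"{path}: expected columns concept_id, doc_id")
    out: Dict[str, Set[str]] = {}
    for c, d in rows:
        out.setdefault(c, set()).add(d)
    return out


def write_concept_links(path: str, links: Mapping[str, Set[str]]) -> None:
    rows = [(c, d) for c in sorted(links) for d in sorted(links[c])]
    write_tsv(path, ["concept_id", "doc_id"], rows)


def write_enrichment(path: str, rows: Iterable[EnrichmentRow],
                     params: Mapping[str, object] | None = None) -> None:
    out = [
        (r.concept_id, r.k, r.n, r.K, r.N, f"{r.fold:.6g}",
         f"{r.p_value:.6g}", f"{r.q_value:.6g}")
        for r in rows
    ]
    write_tsv(path, ["concept_id", "k", "n", "K", "N", "fold", "p_value", "q_value"],
              out, params)


# -- voxel grids ------------------------------------------------------------

def write_expression(path: str, grid: ExpressionGrid) -> None:
    rows = [
        [g] + [f"{v:.8g}" for v in grid.values[i]]
        for i, g in enumerate(grid.genes)
    ]
    write_tsv(path, ["gene_id"] + list(grid.voxel_ids), rows)


def read_expression(path: str) -> ExpressionGrid:
    if path.endswith(".mtx"):
        return _read_expression_mtx(path)
    header, rows, _ = read_tsv(path)
    if not header or header[0] != "gene_id":
        raise FormatError(f"{path}: first column must be gene_id")
    voxel_ids = header[1:]
    genes = [r[0] for r in rows]
    try:
        values = np.array([[float(v) for v in r[1:]] for r in rows])
    except ValueError as e:
        raise FormatError(f"{path}: non-numeric expression value: {e}") from e
    return ExpressionGrid(genes, voxel_ids, values)


def _read_expression_mtx(path: str) -> ExpressionGrid:
    """Sparse MatrixMarket matrix with companion <stem>.genes.txt and
    <stem>.voxels.txt id files (one id per line)."""
    from scipy.io import mmread

    stem = path[: -len(".mtx")]
    values = np.asarray(mmread(path).todense())
    with open(stem + ".genes.txt", encoding="utf-8") as fh:
        genes = [l.strip() for l in fh if l.strip()]
    with open(stem + ".voxels.txt", encoding="utf-8") as fh:
        voxels = [l.strip() for l in fh if l.strip()]
    return ExpressionGrid(genes, voxels, values)


def write_structure_map(path: str, smap: StructureMap) -> None:
    write_tsv(path, ["voxel_id", "structure_id"], sorted(smap.assignment.items()))


def read_structure_map(path: str) -> StructureMap:
    header, rows, _ = read_tsv(path)
    if header != ["voxel_id", "structure_id"]:
        raise FormatError(f"{path}: expected columns voxel_id, structure_id")
    return StructureMap({v: s for v, s in rows})


def write_scores(path: str, scores: Iterable[StructureScore],
                 params: Mapping[str, object] | None = None) -> None:
    rows = [
        (s.gene_id, s.structure_id, f"{s.structure_mean:.8g}",
         f"{s.brain_mean:.8g}", f"{s.fold:.8g}" if s.fold is not None else "NA")
        for s in scores
    ]
    write_tsv(path, ["gene_id", "structure_id", "structure_mean", "brain_mean", "fold"],
              rows, params)
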