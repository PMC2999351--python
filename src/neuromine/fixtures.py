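"""Deterministic synthetic corpora and voxel atlases with planted truth.

Every generator is a pure function of its arguments including the seed, so
fixtures are reproducible byte-for-byte and nothing has to be downloaded.
Corpora are distractor sentences with term mentions inserted at recorded
offsets; atlases are voxel grids with genes elevated on chosen structures so
the expected structure/whole-brain fold equals a requested value, under
mean-one multiplicative log-normal noise.  The generators emulate the shape
of Medline records and 200-micron atlas grids, not their token statistics or
spatial autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .lexicon import (DEFAULT_MAX_PERMUTE, DEFAULT_MIN_LENGTH, Lexicon,
                      TermEntry, build_lexicon, generate_variants)
from .matcher import Document, Match
from .text import DEFAULT_STOPWORDS
from .voxel import ExpressionGrid, StructureMap

#: Anatomical terms used by default.  Chosen so that no term's pattern set
#: contains a contiguous sub-sequence of another's (no adversarial overlaps).
DEFAULT_TERMS: List[Tuple[str, str]] = [
    ("locus coeruleus", "C_LC"),
    ("Ammon's horn", "C_AH"),
    ("cerebellum", "C_CB"),
    ("substantia nigra", "C_SN"),
    ("nucleus accumbens", "C_NAC"),
    ("dentate gyrus", "C_DG"),
    ("superior colliculus", "C_SC"),
    ("globus pallidus", "C_GP"),
    ("medial geniculate body", "C_MGB"),
    ("inferior olive", "C_IO"),
    ("caudate putamen", "C_CPU"),
    ("raphe magnus", "C_RM"),
    ("septal area", "C_SEP"),
    ("olfactory bulb", "C_OB"),
    ("piriform cortex", "C_PIR"),
    ("thalamus", "C_TH"),
    ("hypothalamus paraventricular", "C_PVN"),
    ("entorhinal cortex", "C_EC"),
    ("zona incerta", "C_ZI"),
    ("red nucleus", "C_RN"),
]

#: Filler vocabulary for distractor sentences; shares no token (nor any
#: inflectional variant) with the default term list and contains no stopword,
#: so planted mentions are the only matches and never merge across fillers.
DISTRACTOR_WORDS: List[str] = [
    "study", "result", "method", "analysis", "observed", "during", "level",
    "signal", "change", "report", "measure", "datum", "value", "increase",
    "pattern", "sample", "group", "model", "effect", "between", "subject",
    "response", "control", "activity", "function", "process", "finding",
    "evidence", "approach", "protocol", "baseline", "outcome", "variable",
    "animal", "tissue", "assay", "marker", "profile", "density", "volume",
    "across", "within", "after", "before", "compared", "showed", "revealed",
    "suggest", "indicate", "examined", "recorded", "treated", "tested",
]


@dataclass
class CorpusTruth:
    """A synthetic corpus plus everything needed to verify a tagger on it."""

    documents: List[Document]
    mentions: List[Match]
    concept_doc_sets: Dict[str, Set[str]]
    term_entries: List[TermEntry]
    mesh_to_concept: Dict[str, str]
    mesh_links: Dict[str, Set[str]]
    stopwords: frozenset = DEFAULT_STOPWORDS
    max_permute_tokens: int = DEFAULT_MAX_PERMUTE

    def lexicon(self) -> Lexicon:
        return build_lexicon(
            self.term_entries,
            stopwords=self.stopwords,
            min_length=DEFAULT_MIN_LENGTH,
            max_permute_tokens=self.max_permute_tokens,
        )

    def validate(self) -> None:
        docs = {d.doc_id: d for d in self.documents}
        for m in self.mentions:
            text = docs[m.doc_id].field_text(m.field)
            if text[m.char_start:m.char_end] != m.matched_text:
                raise AssertionError(f"mention span does not re-slice: {m}")


@dataclass
class AtlasTruth:
    """A synthetic voxel atlas plus its planted signal bookkeeping."""

    grid: ExpressionGrid
    smap: StructureMap
    planted: Dict[Tuple[str, str], float] = field(default_factory=dict)
    modules: List[List[str]] = field(default_factory=list)

    def validate(self) -> None:
        genes = set(self.grid.genes)
        structs = self.smap.structures
        for g, s in self.planted:
            if g not in genes or s not in structs:
                raise AssertionError(f"planted pair ({g}, {s}) missing from atlas")
        for mod in self.modules:
            if not set(mod) <= genes:
                raise AssertionError("module member missing from grid")


def _sentence(rng: np.random.Generator, words: Sequence[str], n: int) -> List[str]:
    return [words[i] for i in rng.integers(0, len(words), size=n)]


def make_corpus(
    n_docs: int,
    lexicon_terms: Optional[Sequence[Tuple[str, str]]] = None,
    mention_rate: float = 2.0,
    distractor_vocab: Optional[Sequence[str]] = None,
    seed: int = 0,
    mesh_fraction: float = 0.2,
    stopwords: frozenset = DEFAULT_STOPWORDS,
    max_permute_tokens: int = DEFAULT_MAX_PERMUTE,
) -> CorpusTruth:
    """Corpus of distractor text with ``round(mention_rate * n_docs)`` term
    mentions planted at known offsets, plus MeSH-only links on a fraction of
    documents.

    Mention surface forms are drawn uniformly from each term's full variant
    set (inflections and permuted orders included).  Mentions are planted in
    abstracts, each inside its own sentence and flanked by distractor words,
    so they never merge.  ``mesh_fraction`` of documents get one MeSH heading
    mapped to a random concept (location-free links).
    """
    if n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    terms = list(lexicon_terms if lexicon_terms is not None else DEFAULT_TERMS)
    if not terms:
        raise ValueError("term list is empty")
    words = list(distractor_vocab if distractor_vocab is not None else DISTRACTOR_WORDS)
    rng = np.random.default_rng(seed)

    entries = [TermEntry(t, c, "synthetic") for t, c in terms]
    variants = {
        c: sorted(generate_variants(t, stopwords, max_permute_tokens))
        for t, c in terms
    }
    concepts = [c for _, c in terms]
    mesh_to_concept = {f"MeSH {c}": c for c in concepts}

    total_mentions = int(round(mention_rate * n_docs))
    doc_of_mention = rng.integers(0, n_docs, size=total_mentions)

    documents: List[Document] = []
    mentions: List[Match] = []
    concept_docs: Dict[str, Set[str]] = {c: set() for c in concepts}
    mesh_links: Dict[str, Set[str]] = {}

    for d in range(n_docs):
        doc_id = f"PMID{d:06d}"
        title = " ".join(_sentence(rng, words, int(rng.integers(3, 7)))).capitalize() + "."
        n_here = int(np.sum(doc_of_mention == d))
        parts: List[str] = []
        pos = 0
        sent_idx = 0
        doc_mentions: List[Match] = []
        for _ in range(n_here):
            ci = int(rng.integers(0, len(concepts)))
            concept = concepts[ci]
            surface = " ".join(variants[concept][int(rng.integers(0, len(variants[concept])))])
            pre = _sentence(rng, words, int(rng.integers(1, 4)))
            post = _sentence(rng, words, int(rng.integers(1, 4)))
            lead = " ".join(pre).capitalize() + " "
            tail = " " + " ".join(post) + "."
            start = pos + len(lead)
            sentence = lead + surface + tail
            doc_mentions.append(
                Match(doc_id, concept, "abstract", start, start + len(surface),
                      surface, sent_idx)
            )
            concept_docs[concept].add(doc_id)
            parts.append(sentence)
            pos += len(sentence) + 1  # joined with one space
            sent_idx += 1
        # at least one pure-distractor sentence so no abstract is empty
        for _ in range(int(rng.integers(1, 3))):
            parts.append(" ".join(_sentence(rng, words, int(rng.integers(4, 9)))).capitalize() + ".")
        abstract = " ".join(parts)
        mesh_terms: Tuple[str, ...] = ()
        if rng.random() < mesh_fraction:
            concept = concepts[int(rng.integers(0, len(concepts)))]
            mesh_terms = (f"MeSH {concept}",)
            mesh_links.setdefault(doc_id, set()).add(concept)
            concept_docs[concept].add(doc_id)
        documents.append(Document(doc_id, title, abstract, mesh_terms))
        mentions.extend(doc_mentions)

    truth = CorpusTruth(
        documents=documents,
        mentions=sorted(mentions),
        concept_doc_sets={c: s for c, s in concept_docs.items() if s},
        term_entries=entries,
        mesh_to_concept=mesh_to_concept,
        mesh_links=mesh_links,
        stopwords=stopwords,
        max_permute_tokens=max_permute_tokens,
    )
    truth.validate()
    return truth


def tile_structures(n_voxels: int, n_structures: int) -> List[int]:
    """Assign voxels (in flat order) to n_structures contiguous near-equal
    blocks; returns the structure index per voxel."""
    if not 1 <= n_structures <= n_voxels:
        raise ValueError("need 1 <= n_structures <= n_voxels")
    bounds = np.linspace(0, n_voxels, n_structures + 1).astype(int)
    out = np.empty(n_voxels, dtype=int)
    for s in range(n_structures):
        out[bounds[s]:bounds[s + 1]] = s
    return out.tolist()


def make_voxel_atlas(
    n_genes: int,
    grid_dims: Tuple[int, int, int] = (10, 10, 10),
    n_structures: int = 25,
    planted: Sequence[Tuple[str, str, float]] = (),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> AtlasTruth:
    """Voxel grid with baseline expression 1.0 and genes elevated on chosen
    structures so the expected structure/whole-brain fold equals the request.

    With structure voxel fraction f, a fold F against a unit background needs
    F·f < 1 (structure value F(1-f)/(1-F·f)); at F == 1/f the background is
    set to 0 (the maximal construction); F > 1/f is unattainable and raises.
    Noise is element-wise mean-one log-normal with shape ``noise_sigma``.
    """
    nx, ny, nz = grid_dims
    n_vox = nx * ny * nz
    genes = [f"g{i:05d}" for i in range(n_genes)]
    voxel_ids = [f"v{j:05d}" for j in range(n_vox)]
    coords = {
        f"v{j:05d}": (j % nx, (j // nx) % ny, j // (nx * ny)) for j in range(n_vox)
    }
    struct_of = tile_structures(n_vox, n_structures)
    assignment = {voxel_ids[j]: f"S{struct_of[j]:03d}" for j in range(n_vox)}

    values = np.ones((n_genes, n_vox))
    gene_index = {g: i for i, g in enumerate(genes)}
    struct_cols = {
        s: np.array([j for j in range(n_vox) if assignment[voxel_ids[j]] == s])
        for s in set(assignment.values())
    }
    planted_map: Dict[Tuple[str, str], float] = {}
    for gene, struct, fold in planted:
        if gene not in gene_index:
            raise ValueError(f"planted gene {gene!r} not in grid")
        if struct not in struct_cols:
            raise ValueError(f"planted structure {struct!r} not in grid")
        if fold < 1:
            raise ValueError("planted folds must be >= 1")
        cols = struct_cols[struct]
        f = len(cols) / n_vox
        i = gene_index[gene]
        if fold * f > 1 + 1e-12:
            raise ValueError(
                f"fold {fold} unattainable on a structure holding fraction "
                f"{f:.3f} of voxels (need fold <= 1/f = {1 / f:.2f})"
            )
        if abs(fold * f - 1) <= 1e-12:
            values[i, :] = 0.0
            values[i, cols] = 1.0
        else:
            values[i, :] = 1.0
            values[i, cols] = fold * (1 - f) / (1 - fold * f)
        planted_map[(gene, struct)] = fold

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.lognormal(mean=-noise_sigma**2 / 2, sigma=noise_sigma,
                              size=values.shape)
        values = values * noise

    truth = AtlasTruth(
        grid=ExpressionGrid(genes, voxel_ids, values, coords),
        smap=StructureMap(assignment),
        planted=planted_map,
    )
    truth.validate()
    return truth


def make_corr_modules(
    n_genes: int,
    module_sizes: Sequence[int],
    latent_profiles: Optional[Sequence[np.ndarray]] = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_voxels: int = 50,
) -> AtlasTruth:
    """Expression grid containing correlated gene modules.

    Module members are positive-slope affine transforms of their module's
    latent voxel profile plus additive Gaussian noise (so ``noise_sigma=0``
    gives exact within-module r = 1); remaining genes are independent noise.
    """
    if sum(module_sizes) > n_genes:
        raise ValueError("module sizes exceed gene count")
    rng = np.random.default_rng(seed)
    if latent_profiles is None:
        latent_profiles = [rng.uniform(1.0, 5.0, size=n_voxels)
                           for _ in module_sizes]
    if len(latent_profiles) != len(module_sizes):
        raise ValueError("one latent profile per module required")
    for lp in latent_profiles:
        if np.ptp(np.asarray(lp)) == 0:
            raise ValueError("latent profile is constant")
    n_voxels = len(np.asarray(latent_profiles[0]))

    genes = [f"g{i:05d}" for i in range(n_genes)]
    values = rng.uniform(0.5, 5.0, size=(n_genes, n_voxels))
    modules: List[List[str]] = []
    gi = 0
    for size, latent in zip(module_sizes, latent_profiles):
        latent = np.asarray(latent, dtype=float)
        members = []
        for _ in range(size):
            a = rng.uniform(1.0, 2.0)
            b = rng.uniform(0.5, 2.0)
            noise = rng.normal(0.0, noise_sigma, size=n_voxels) if noise_sigma > 0 else 0.0
            values[gi] = np.maximum(a + b * latent + noise, 0.0)
            members.append(genes[gi])
            gi += 1
        modules.append(members)

    voxel_ids = [f"v{j:05d}" for j in range(n_voxels)]
    assignment = {v: "S000" for v in voxel_ids}
    truth = AtlasTruth(
        grid=ExpressionGrid(genes, voxel_ids, values),
        smap=StructureMap(assignment),
        modules=modules,
    )
    truth.validate()
    return truth
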