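# Methods

This note records the models, rules and design choices behind each
component, the parameters that matter, and what the synthetic-data tests do
and do not establish about behaviour on real literature and atlas data.

## Lexicon compilation

Term tables carry one row per surface string per source vocabulary, with an
abbreviation flag.  Compilation proceeds in four stages:

1. **Unification.**  An optional concept map rewrites (term, source) pairs
   to canonical concept ids, emulating the cross-atlas mapping of
   nomenclatures onto one reference ontology.  Without a mapping the row's
   own id passes through; under `strict` an unmapped pair is an error.
   Duplicate (term, concept) pairs collapse to one.
2. **Filtering.**  Abbreviations are excluded and a term must have at least
   `min_length` = 5 non-whitespace characters.  Both rules exist to cut
   false positives: short strings and abbreviations ("CA1") are wildly
   ambiguous in running text.  Character counting ignores whitespace so
   that multi-word terms are judged by their letter content.
3. **Variant generation.**  Tokens are maximal runs of letters, digits and
   apostrophes; anything else separates tokens, which makes hyphenated and
   spaced spellings identical.  Tokens are lowercased, stopwords removed,
   and each content token expanded to its inflectional variants by a fixed
   rule set: regular plural (+s; +es after s, x, z, ch, sh; consonant-y →
   ies) and its inverse, with possessives, digit-bearing tokens and the
   Latin-style -us/-is/-ss endings left untouched.  The rule set is
   deliberately small and closed: it is deterministic, testable, and errs
   toward missing an irregular inflection rather than inventing a spurious
   one.
4. **Permutation.**  All orderings of the content tokens are emitted when
   there are at most `max_permute_tokens` = 4 of them ("gyrus dentates" for
   "dentate gyrus"); longer terms keep only their original order, bounding
   the factorial blowup at 24 orderings per variant combination.

The default stopword list is a small English function-word set
({the, of, a, an, in, on, and, or}); it is configurable because any
realistic deployment would substitute a corpus-derived high-frequency list.
Patterns map to *sets* of concept ids, so an ambiguous string retains all
its senses; no disambiguation is attempted.

Inflection is handled entirely on the lexicon side (every variant is a
stored pattern), so the matcher needs only case-folding and stopword
skipping at scan time; the two designs are behaviourally equivalent and
this one keeps the matcher a pure dictionary lookup.

## Matching

Titles and abstracts are scanned independently.  Candidate windows start
and end on content tokens; stopwords interior to a window are skipped for
lookup but included in the reported character span.  Offsets are 0-based,
half-open, in code points, and `text[start:end] == matched_text` always
holds.  A match never crosses a sentence boundary; sentences break at
`.!?` followed by whitespace and an uppercase letter or end of text, a
cheap rule that deliberately keeps "E. coli grows." whole.  Best-match
resolution suppresses any span strictly contained in another emitted span
in the same field; overlapping but non-nested spans are both kept, and one
match is emitted per (span, concept).  Complexity is O(tokens ×
max-pattern-length) hash lookups per field.

MeSH headings are matched by exact case-insensitive string lookup and yield
record-level links without positions; consequently they participate in
abstract-level co-occurrence only.  Document↔concept linkage is the union
of text matches and MeSH links, counted once per document.

## Enrichment

Counting is document-level throughout: a concept counts once per document
no matter how many mentions it has, matching the pre-computed per-document
background frequencies the ranking is designed around.  The two scores are
the fold ratio (k/n)/(K/N) and the hypergeometric upper tail P(X ≥ k)
(scipy's `hypergeom.sf`, computed in log space); Benjamini–Hochberg
adjustment is optional.  Sorting is by the chosen score with concept-id
tie-breaks so output order is total and reproducible.  A concept present in
the foreground but absent from a user-supplied background gets K floored to
k with a warning — visible, not silent, and it yields the most conservative
finite fold.

## Voxel structure fold

The statistic is the ratio of a gene's arithmetic mean expression over a
structure's voxels to its mean over *all* grid voxels, including unassigned
and zero-expression voxels.  `epsilon` (default 0) defines when the
whole-brain mean is too small for the ratio to be meaningful; only
exactly-zero means are excluded by default since zero division is the only
forced exclusion.  Structures are flat label sets — no hierarchy rollup —
and voxel coordinates are carried but unused by scoring.  `top_genes`
sorts by fold with gene-id tie-breaks and defaults to k = 20, the
conventional shortlist size for per-structure gene panels.

The fold has a hard ceiling of 1/f, where f is the structure's fraction of
all voxels: a gene expressed *only* in the structure attains it.  The atlas
generator refuses planted folds above this ceiling rather than silently
delivering less than asked.

## Correlation networks

Edges carry Pearson's r over all voxels — the natural choice for additive
expression-energy values; a Spearman hook would be the first extension for
heavy-tailed data.  Ranking uses signed r descending (an `absolute` flag
ranks by |r|), since "highly correlated" most plainly means positive
association.  Constant genes have undefined correlation: they are skipped
as partners and an error as the query.  `expand` is a pure function
returning a new network equal to the union of the old one and the query
gene's top-m correlates, hence idempotent; r is clamped to [−1, 1] against
floating-point overshoot.

## Dataset sharing

Storage is one SQLite file with exactly five tables: user accounts (user →
groups), share permissions (dataset → principal), dataset definitions,
data rows, and update history.  Design choices:

- **Creator-only writes.**  Read access is grantable to `user:<id>`,
  `group:<id>` or `public`; writing and permission management stay with the
  creator — the most conservative policy consistent with creator-managed
  sharing.
- **Replayable history.**  Every create/update/delete appends one event
  recording application, change type, free-text parameters, timestamp and
  the row payload, so the current row set is reconstructible from the log
  alone (verified by property test).  Deletion is a tombstone plus a delete
  event, keeping replay total.
- **Trusted identity.**  Callers supply their user id; authentication and
  sessions are an application concern outside this layer.
- **Exchange format.**  Export/import is a canonical JSON document (sorted
  keys, no incidental whitespace) with title, field names, rows, creator,
  parameters and description; export → import → export is byte-identical.

## Synthetic data

`make_corpus` builds documents from a packaged distractor vocabulary
disjoint from every term token (and every inflectional variant), inserts
`round(mention_rate × n_docs)` mentions whose surface forms are drawn
uniformly from each term's full variant set, records exact spans as ground
truth, and gives a configurable fraction of documents a MeSH-only link.
Each mention sits in its own sentence flanked by distractor words, so
planted mentions can neither merge nor collide — the "no adversarial
overlaps" regime in which recall and precision are provably 1.0.  Defaults
(100 documents per simulated corpus batch, 2 mentions per document on
average, 20% MeSH fraction) are sized so that co-occurrence and enrichment
have non-trivial counts while the whole suite runs in seconds.

`make_voxel_atlas` uses baseline expression 1.0 and solves exactly for the
structure value that makes the expected ratio-of-means equal the requested
fold; noise is element-wise mean-one multiplicative log-normal (expression
energies are non-negative, and mean-one noise leaves expected means — and
hence expected folds — unchanged).  The default geometry is a 10×10×10
grid tiled into 25 contiguous structures (voxel fraction 0.04), which
admits planted folds up to 25.  The recovery study plants 5 genes at fold
20 with σ = 0.3 among 100 genes and asks `top_genes` for exactly 5.

`make_corr_modules` makes module members positive-slope affine transforms
of a shared latent voxel profile plus additive Gaussian noise (zero noise →
exact collinearity, r = 1), with non-members independent uniform noise.
Values are clipped at zero to respect grid non-negativity; with the default
offsets the clip is essentially never active.

**What passing tests show — and don't.**  The fixtures demonstrate
correctness of the mechanics (locations, counting, statistics, permissions)
with planted truth.  They do not mimic real Medline token statistics,
ambiguous term senses, OCR noise, or the spatial autocorrelation and
missingness of real atlas data; real-corpus precision will be below 1.0
for exactly the reasons (ambiguity, context) that dictionary matching
cannot resolve.

## Numerical and scale choices

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give byte-identical outputs.  Hypergeometric exactness is checked
against explicit combinatorial sums on the full grid N ≤ 25, and one case
against literal enumeration of all C(20,6) draws.  Correlations are checked
against the textbook sum formula to 1e-9 on 20×50 grids.  The recovery
study uses 200 replicates of a 100 × 1000 grid, large enough for a stable
rate estimate yet a few seconds of compute.  TSV output uses `%.8g`
formatting (`%.6g` for p-values), comment headers with tool version and
parameters, and atomic temp-file-and-rename writes.

## Known limitations

- No word-sense disambiguation: an ambiguous string maps to all its
  concepts.
- The inflection rules are regular-English only; irregular plurals
  (nuclei, cortices) surface as their own lexicon rows or not at all.
- Permutation matching can create false surface orders for long terms in
  adversarial text; the cap at 4 tokens limits but does not remove this.
- Enrichment assumes the foreground is drawn from the background corpus;
  mixed-corpus foregrounds violate the hypergeometric model.
- The sharing store trusts caller-supplied identity and has no group
  administration model; groups are loaded as data.
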