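import itertools
import math

import pytest

from neuromine.lexicon import (Lexicon, MappingError, TermEntry, VariantError,
                               build_lexicon, filter_terms, generate_variants,
                               term_length, unify_terms)
from neuromine.text import DEFAULT_STOPWORDS, token_variants, tokenize

STOP = frozenset({"the", "of"})


class TestUnify:
    def test_concept_map_forces_canonical_ids(self):
        entries = [
            TermEntry("Ammon's horn", "A1", "atlasA"),
            TermEntry("Ammons horn", "B7", "atlasB"),
        ]
        cmap = {("Ammon's horn", "atlasA"): "C_AH", ("Ammons horn", "atlasB"): "C_AH"}
        out = unify_terms(entries, cmap)
        assert [e.concept_id for e in out] == ["C_AH", "C_AH"]
        assert len(out) == 2

    def test_empty_input(self):
        assert unify_terms([], {}) == []

    def test_duplicates_collapse_after_mapping(self):
        # 10 entries; mapping makes 3 of them duplicate (term, concept) pairs
        entries = [TermEntry(f"term {i}", f"X{i}", "s") for i in range(7)]
        entries += [
            TermEntry("term 0", "Y0", "t"),
            TermEntry("term 1", "Y1", "t"),
            TermEntry("term 2", "Y2", "t"),
        ]
        cmap = {(f"term {i}", "t"): f"X{i}" for i in range(3)}
        out = unify_terms(entries, cmap)
        # brute-force de-duplication oracle
        seen, expected = set(), 0
        for e in entries:
            cid = cmap.get((e.term, e.source), e.concept_id)
            if (e.term, cid) not in seen:
                seen.add((e.term, cid))
                expected += 1
        assert len(out) == expected == 7

    def test_strict_policy_raises_on_unmapped(self):
        with pytest.raises(MappingError, match="atlasZ"):
            unify_terms([TermEntry("foo bar", "X", "atlasZ")], {}, strict=True)


class TestFilter:
    def test_abbreviation_and_length_rules(self):
        entries = [
            TermEntry("CA1", "C1", "s", is_abbreviation=True),
            TermEntry("arch", "C2", "s"),  # 4 characters
            TermEntry("locus coeruleus", "C3", "s"),
        ]
        out = filter_terms(entries, min_length=5)
        assert [e.concept_id for e in out] == ["C3"]

    def test_length_counts_non_whitespace(self):
        assert term_length("a b c") == 3
        # 5 non-whitespace characters spread over two words passes
        out = filter_terms([TermEntry("ab cde", "C", "s")], min_length=5)
        assert len(out) == 1

    def test_abbreviation_kept_when_exclusion_off(self):
        e = TermEntry("CA1 field", "C", "s", is_abbreviation=True)
        assert filter_terms([e], exclude_abbreviations=False) == [e]

    def test_monotone_in_min_length(self):
        entries = [TermEntry(t, f"C{i}", "s")
                   for i, t in enumerate(["abcd", "abcde", "abcdef", "abc defg"])]
        counts = [len(filter_terms(entries, min_length=m)) for m in range(1, 10)]
        assert counts == sorted(counts, reverse=True)


class TestVariants:
    def test_two_token_orderings(self):
        pats = generate_variants("Ammon's horn", STOP, 4)
        assert ("ammon's", "horn") in pats
        assert ("horn", "ammon's") in pats

    def test_three_token_term_has_all_six_orderings(self):
        pats = generate_variants("nucleus of the solitary tract", STOP, 4)
        base = ("nucleus", "solitary", "tract")
        for perm in itertools.permutations(base):
            assert perm in pats

    def test_single_token_plural_pair(self):
        assert generate_variants("cerebellum", STOP, 4) == {
            ("cerebellum",), ("cerebellums",)
        }

    def test_hyphen_space_equivalence(self):
        assert generate_variants("locus-coeruleus", STOP, 4) == \
            generate_variants("locus coeruleus", STOP, 4)

    def test_permutation_cap_keeps_original_order_only(self):
        term = "alpha beta gamma delta epsilon"
        pats = generate_variants(term, STOP, max_permute_tokens=4)
        orders = {tuple(p.index(v) for v in ("alpha", "beta", "gamma", "delta", "epsilon"))
                  for p in pats if set(p) == {"alpha", "beta", "gamma", "delta", "epsilon"}}
        assert orders == {(0, 1, 2, 3, 4)}

    def test_stopword_only_term_is_an_error(self):
        with pytest.raises(VariantError):
            generate_variants("of the", STOP, 4)


class TestBuildLexicon:
    def test_pattern_multimap_for_shared_string(self):
        entries = [
            TermEntry("capsule zone", "C1", "a"),
            TermEntry("capsule zone", "C2", "b"),
        ]
        lex = build_lexicon(entries, STOP)
        assert lex.patterns[("capsule", "zone")] == {"C1", "C2"}

    def test_two_content_tokens_give_at_least_two_patterns(self):
        lex = build_lexicon([TermEntry("locus coeruleus", "C1", "s")], STOP)
        assert len(lex.patterns) >= 2
        assert ("coeruleus", "locus") in lex.patterns

    def test_empty_retained_set_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            lex = build_lexicon([TermEntry("arch", "C", "s")], STOP)
        assert lex.patterns == {}

    def test_pattern_count_matches_independent_regeneration(self):
        # 100 synthetic entries with distinct token universes per term
        entries = [
            TermEntry(f"alpha{i} beta{i} of gamma{i}", f"C{i}", "s")
            for i in range(100)
        ]
        lex = build_lexicon(entries, STOP)
        # independent per-term enumeration: inflection sets per token, then
        # permutations, summed (token universes are disjoint so no collisions)
        total = 0
        for e in entries:
            toks = [t.lower() for t, _, _ in tokenize(e.term) if t.lower() not in STOP]
            combos = 1
            for t in toks:
                combos *= len(token_variants(t))
            total += combos * math.factorial(len(toks))
        assert len(lex.patterns) == total

    def test_idempotent_on_own_provenance(self):
        entries = [TermEntry("dentate gyrus", "C1", "s"),
                   TermEntry("red nucleus", "C2", "s")]
        lex = build_lexicon(entries, STOP)
        prov_terms = {e for es in lex.provenance.values() for e in es}
        lex2 = build_lexicon(sorted(prov_terms, key=lambda e: e.term), STOP)
        assert lex2.patterns == lex.patterns

    def test_invariants_no_stopword_only_pattern_and_min_length(self):
        entries = [TermEntry(t, f"C{i}", "s") for i, t in enumerate(
            ["dentate gyrus", "the red nucleus", "zona incerta of the brain"])]
        lex = build_lexicon(entries, DEFAULT_STOPWORDS)
        for pat in lex.patterns:
            assert pat, "empty pattern"
            assert any(tok not in lex.stopwords for tok in pat)
            for e in lex.provenance[pat]:
                assert term_length(e.term) >= lex.min_length
        assert set().union(*lex.patterns.values()) == {
            cid for es in lex.provenance.values() for cid in
            (e.concept_id for e in es)
        }
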