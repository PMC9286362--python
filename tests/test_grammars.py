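"""Grammar generation, membership, enumeration, and shortcut rules."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import aglearn as ag
from aglearn.grammars import parse_pattern

ALL_GRAMMARS = ("ABNA", "MIRROR", "COPY", "WARMUP_ABN")


def canonical_text(gid: str, cats: str) -> str:
    """Place markers in the grammar's canonical positions around a category
    string — an independent constructor used as test input."""
    if gid == "ABNA":
        return f"{cats[0]}|{cats[1:-1]}|{cats[-1]}"
    if gid in ("MIRROR", "COPY"):
        h = len(cats) // 2
        return f"{cats[:h]}|{cats[h:]}"
    return cats


class TestGeneration:
    def test_abna_is_deterministic_category_string(self, rng):
        s = ag.generate_string(ag.grammar("ABNA"), 2, rng)
        assert str(s) == "A|BB|A"
        assert s.categories == "ABBA"

    def test_warmup_alternates_categories(self, rng):
        s = ag.generate_string(ag.grammar("WARMUP_ABN"), 3, rng)
        assert str(s) == "ABABAB"

    @pytest.mark.parametrize("gid", ALL_GRAMMARS)
    @pytest.mark.parametrize("n", range(1, 7))
    def test_generated_strings_lie_in_enumerated_language(self, gid, n, rng):
        g = ag.grammar(gid)
        lang = ag.enumerate_language(g, n)
        for _ in range(20):
            assert ag.generate_string(g, n, rng) in lang

    def test_palindromic_half_exclusion(self, rng):
        g = ag.grammar("MIRROR")
        for _ in range(50):
            s = ag.generate_string(g, 3, rng, exclude_palindrome=True)
            half = s.categories[:3]
            assert half != half[::-1]

    def test_invalid_inputs_raise(self, rng):
        with pytest.raises(KeyError):
            ag.generate_string(ag.GrammarSpec("ENDS_A"), 2, rng)
        with pytest.raises(ValueError):
            ag.generate_string(ag.grammar("COPY"), 0, rng)


class TestMembership:
    @pytest.mark.parametrize("text,gid,expected", [
        ("AAB|BAA", "MIRROR", True),
        ("AAB|BAA", "COPY", False),       # halves unequal
        ("ABA|ABA", "MIRROR", True),      # palindromic half satisfies both
        ("ABA|ABA", "COPY", True),
        ("A|BB|A", "ABNA", True),
        ("A|BB|B", "ABNA", False),
        ("A|BB|", "ABNA", False),         # incomplete dependency
        ("ABAB", "WARMUP_ABN", True),
        ("ABBA", "WARMUP_ABN", False),
    ])
    def test_examples(self, text, gid, expected):
        assert ag.is_member(parse_pattern(text), ag.grammar(gid)) is expected

    def test_displaced_marker_is_ungrammatical_not_an_error(self):
        # correct categories, marker off centre
        assert not ag.is_member(parse_pattern("AABB|AA"), ag.grammar("MIRROR"))
        assert ag.is_member(parse_pattern("AABB|AA"), ag.grammar("MIRROR"),
                            check_markers=False)

    @pytest.mark.parametrize("gid", ALL_GRAMMARS)
    @pytest.mark.parametrize("n", range(1, 7))
    def test_membership_agrees_with_enumeration_oracle(self, gid, n):
        """Exhaustive equivalence: over every category string of the right
        length with canonical markers, is_member is true exactly on the
        enumerated language."""
        g = ag.grammar(gid)
        lang = {s.categories for s in ag.enumerate_language(g, n)}
        length = n + 2 if gid == "ABNA" else 2 * n
        for cats in map("".join, itertools.product("AB", repeat=length)):
            s = parse_pattern(canonical_text(gid, cats))
            assert ag.is_member(s, g) == (cats in lang)

    def test_exemplar_relabeling_is_ignored(self, rng):
        plain = parse_pattern("AAB|BAA")
        decorated = parse_pattern("A2A1B3|B1A4A4")
        for gid in ("MIRROR", "COPY"):
            g = ag.grammar(gid)
            assert ag.is_member(plain, g) == ag.is_member(decorated, g)


class TestEnumeration:
    @pytest.mark.parametrize("gid,n,size", [
        ("MIRROR", 3, 8), ("COPY", 3, 8), ("ABNA", 5, 1), ("WARMUP_ABN", 4, 1),
    ])
    def test_language_sizes(self, gid, n, size):
        assert len(ag.enumerate_language(ag.grammar(gid), n)) == size

    def test_copy_mirror_overlap_is_palindromic_halves(self):
        copy = {s.categories for s in ag.enumerate_language(ag.grammar("COPY"), 2)}
        mirror = {s.categories for s in ag.enumerate_language(ag.grammar("MIRROR"), 2)}
        assert copy & mirror == {"AAAA", "BBBB"}

    @pytest.mark.parametrize("n", range(2, 7))
    def test_overlap_fraction_is_two_to_ceil_half(self, n):
        """P(copy string is also mirror) = 2^ceil(n/2) / 2^n: the first half
        must be a palindrome."""
        copy = {s.categories for s in ag.enumerate_language(ag.grammar("COPY"), n)}
        mirror = {s.categories for s in ag.enumerate_language(ag.grammar("MIRROR"), n)}
        assert len(copy & mirror) / len(copy) == 2 ** -(n // 2)

    def test_cap_enforced(self):
        with pytest.raises(ValueError):
            ag.enumerate_language(ag.grammar("MIRROR"), 9)


class TestAlternateRules:
    @pytest.mark.parametrize("text,rule,expected", [
        ("A|BB|A", "ENDS_A", True),
        ("B|BB|A", "ENDS_A", True),
        ("A|BB|B", "ENDS_A", False),
        ("A|BB|B", "BEGINS_A", True),
        ("AAB|BAA", "EDGE_MATCH", True),
        ("AAB|BAB", "EDGE_MATCH", False),
        ("AAB|ABA", "HALF_COUNT_MATCH", True),
        ("AAB|BBA", "HALF_COUNT_MATCH", False),
    ])
    def test_simple_rules(self, text, rule, expected):
        assert ag.alt_is_member(parse_pattern(text), ag.alternate(rule)) is expected

    def test_marker_ok_and_legal_length_are_target_relative(self):
        mirror_ok = ag.alternate("MARKER_OK", target="MIRROR")
        assert ag.alt_is_member(parse_pattern("AAB|BBB"), mirror_ok)
        assert not ag.alt_is_member(parse_pattern("AABB|BB"), mirror_ok)
        legal = ag.alternate("LEGAL_LENGTH", target="MIRROR")
        assert ag.alt_is_member(parse_pattern("ABAB"), legal)
        assert not ag.alt_is_member(parse_pattern("ABA"), legal)   # odd length

    def test_bigram_familiarity(self):
        rule = ag.alternate("BIGRAM_FAMILIAR", bigrams=frozenset({"AB", "BB", "BA"}))
        assert ag.alt_is_member(parse_pattern("ABBA"), rule)
        assert not ag.alt_is_member(parse_pattern("AABB"), rule)   # AA unseen

    @pytest.mark.parametrize("n", range(1, 7))
    def test_ends_a_implied_by_abna_membership(self, n):
        ends_a = ag.alternate("ENDS_A")
        for s in ag.enumerate_language(ag.grammar("ABNA"), n):
            assert ag.alt_is_member(s, ends_a)

    @pytest.mark.parametrize("text,expected", [
        ("A|BB|A", {"ABNA": True, "ENDS_A": True}),
        ("A|BB|B", {"ABNA": False, "ENDS_A": False}),
        ("B|BB|A", {"ABNA": False, "ENDS_A": True}),
    ])
    def test_classify_all(self, text, expected):
        registry = [ag.grammar("ABNA"), ag.alternate("ENDS_A")]
        assert ag.classify_all(parse_pattern(text), registry) == expected

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            ag.classify_all(parse_pattern("ABAB"), [])

    def test_default_registry_contains_target_and_all_alternates(self):
        reg = ag.default_registry("MIRROR")
        assert [r.id for r in reg] == ["MIRROR", *ag.ALTERNATE_RULE_IDS]


@given(st.lists(st.sampled_from(["A", "B", "A1", "B3", "|", "A12"]),
                min_size=1, max_size=12))
def test_serialization_round_trip(parts):
    text = "".join(parts)
    assert str(parse_pattern(text)) == text
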