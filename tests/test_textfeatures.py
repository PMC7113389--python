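"""Tokenization and the seven surface word features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regaze.textfeatures import (
    DEFAULT_SONORITY_TABLE,
    Lexicon,
    SonorityTable,
    build_feature_table,
    consonant_vowel_quotient,
    higher_freq_neighbors,
    levenshtein,
    load_bundled_sonnets,
    log_frequency,
    orthographic_dissimilarity,
    orthographic_neighbors,
    sonority_score,
    tokenize_poem,
    word_length,
)


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------


class TestTokenize:
    def test_epigraph_line(self):
        toks = tokenize_poem("When to the sessions of sweet silent thought", "s30")
        assert len(toks) == 8
        assert toks[0].norm == "when"
        assert toks[-1].norm == "thought"

    def test_incipit_strips_punctuation(self):
        toks = tokenize_poem("Weary with toil,", "27")
        assert [t.norm for t in toks] == ["weary", "with", "toil"]

    def test_empty_text_errors(self):
        with pytest.raises(ValueError):
            tokenize_poem("", "x")

    def test_contractions_and_hyphens_kept(self):
        toks = tokenize_poem("And art made tongue-tied by authority, 'tis", "66")
        norms = [t.norm for t in toks]
        assert "tongue-tied" in norms
        assert "tis" in norms  # leading apostrophe is edge punctuation

    def test_split_hyphens_option(self):
        toks = tokenize_poem("folly, doctor-like, controlling", "66",
                             split_hyphens=True)
        assert [t.norm for t in toks] == ["folly", "doctor", "like", "controlling"]

    def test_positions_are_line_and_word_numbers(self):
        toks = tokenize_poem("a b\nc", "x")
        assert [(t.line_no, t.word_no) for t in toks] == [(1, 1), (1, 2), (2, 1)]

    def test_nonalpha_line_skipped_without_renumbering_gap(self, caplog):
        toks = tokenize_poem("one two\n***\nthree", "x")
        assert [(t.norm, t.line_no) for t in toks] == [
            ("one", 1), ("two", 1), ("three", 2)]


def test_bundled_sonnets_token_count():
    """The two bundled poems hold 200 tokens with compounds whole, 202 split."""
    assert len(load_bundled_sonnets()) == 200
    assert len(load_bundled_sonnets(split_hyphens=True)) == 202


# ---------------------------------------------------------------------------
# per-word features against hand-computed examples
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "word,expected",
    [("art", 3), ("a", 1), ("o'er", 3), ("tongue-tied", 10)],
)
def test_word_length_counts_letters_only(word, expected):
    assert word_length(word) == expected


def test_log_frequency_add_one():
    lex = Lexicon({"x": 999, "y": 9})
    assert log_frequency("x", lex) == pytest.approx(3.0)
    assert log_frequency("y", lex) == pytest.approx(1.0)
    assert log_frequency("missing", lex) == 0.0


class TestNeighbors:
    def test_coltheart_n(self, toy_lexicon):
        # cat: bat, rat, cot same length, one substitution; cart differs in length
        assert orthographic_neighbors("cat", toy_lexicon) == 3

    def test_single_letter_words(self):
        lex = Lexicon({"a": 1, "i": 2, "o": 3})
        assert orthographic_neighbors("a", lex) == 2

    def test_word_alone(self):
        lex = Lexicon({"zzz": 1, "a": 1})
        assert orthographic_neighbors("zzz", lex) == 0

    def test_higher_freq_neighbors_strict(self, toy_lexicon):
        # cat(10): bat(20) higher, rat(5) lower, cot(10) tie -> 1
        assert higher_freq_neighbors("cat", toy_lexicon) == 1

    def test_symmetry_and_hfn_bound(self, toy_lexicon):
        words = list(toy_lexicon.types())
        for w1 in words:
            for w2 in words:
                if len(w1) == len(w2) and w1 != w2:
                    n1 = orthographic_neighbors(w1, toy_lexicon)
                    in12 = levenshtein(w1, w2) == 1
                    in21 = levenshtein(w2, w1) == 1
                    assert in12 == in21
            assert higher_freq_neighbors(w1, toy_lexicon) <= \
                orthographic_neighbors(w1, toy_lexicon)


class TestLevenshtein:
    def _oracle(self, a, b):
        # independent recursive definition with memoization
        from functools import lru_cache

        @lru_cache(maxsize=None)
        def d(i, j):
            if i == 0:
                return j
            if j == 0:
                return i
            return min(
                d(i - 1, j) + 1,
                d(i, j - 1) + 1,
                d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
            )

        return d(len(a), len(b))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet="abc", max_size=6), st.text(alphabet="abc", max_size=6))
    def test_matches_recursive_oracle(self, a, b):
        assert levenshtein(a, b) == self._oracle(a, b)

    def test_known_distances(self):
        assert levenshtein("art", "cart") == 1
        assert levenshtein("ab", "abc") == 1
        assert levenshtein("ab", "b") == 1


class TestDissimilarity:
    def test_mean_over_other_types(self):
        lex = Lexicon({"ab": 1, "abc": 5, "b": 2})
        assert orthographic_dissimilarity("ab", lex) == pytest.approx(1.0)

    def test_degenerate_lexicon_errors(self):
        lex = Lexicon({"ab": 1})
        with pytest.raises(ValueError):
            orthographic_dissimilarity("ab", lex)


class TestCVQ:
    @pytest.mark.parametrize("word,expected", [("art", 2.0), ("aa", 0.0),
                                               ("rhythm", 5.0)])
    def test_examples(self, word, expected):
        assert consonant_vowel_quotient(word) == pytest.approx(expected)

    def test_no_vowel_yields_nan(self):
        assert math.isnan(consonant_vowel_quotient("shh"))


class TestSonority:
    def test_art_worked_example(self):
        assert round(sonority_score("art"), 2) == 10.39

    def test_default_table_covers_all_ten_ranks(self):
        assert set(DEFAULT_SONORITY_TABLE.ranks.values()) == set(range(1, 11))
        assert set(DEFAULT_SONORITY_TABLE.ranks) == set(
            "abcdefghijklmnopqrstuvwxyz")

    def test_single_vowel(self):
        assert sonority_score("a") == pytest.approx(10.0)

    def test_pat_from_default_table(self):
        assert round(sonority_score("pat"), 2) == 6.93

    def test_case_invariance(self):
        assert sonority_score("Art") == sonority_score("art")

    def test_rank_scaling_multiplies_score(self):
        doubled = SonorityTable({k: 2 * v for k, v in
                                 DEFAULT_SONORITY_TABLE.ranks.items()})
        assert sonority_score("art", doubled) == pytest.approx(
            2 * sonority_score("art"))

    def test_unmappable_symbol_named(self):
        table = SonorityTable({**DEFAULT_SONORITY_TABLE.ranks})
        ranks = dict(DEFAULT_SONORITY_TABLE.ranks)
        del ranks["x"]
        # removing x keeps all 10 ranks present via other letters
        table = SonorityTable(ranks)
        with pytest.raises(KeyError, match="x"):
            sonority_score("box", table)

    def test_phonemic_ng_collapses_digraph(self):
        plain = sonority_score("sing")
        phonemic = sonority_score("sing", SonorityTable(phonemic=True))
        # n(5)+g(2) as letters vs single nasal(5): scores must differ
        assert phonemic != plain


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


class TestFeatureTable:
    def test_one_row_per_token(self, toy_lexicon):
        df = build_feature_table({"p": "cat bat\nrat cot"}, toy_lexicon)
        assert len(df) == 4
        assert list(df["word_no"]) == [1, 2, 1, 2]

    def test_bundled_sonnets_202_rows(self, toy_lexicon):
        toks = load_bundled_sonnets(split_hyphens=True)
        df = build_feature_table(toks, toy_lexicon)
        assert len(df) == 202

    def test_standardized_columns(self, toy_lexicon):
        df = build_feature_table({"p": "cat bat rat\ncot cart cat"}, toy_lexicon,
                                 standardize=True)
        assert df["wl_z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert np.std(df["wl_z"]) == pytest.approx(1.0)

    def test_repeated_words_not_merged(self, toy_lexicon):
        df = build_feature_table({"p": "cat cat"}, toy_lexicon)
        assert len(df) == 2
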