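"""String metrics, candidate selection and n-gram-overlap refinement."""

import string

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from figtext.corrector import (MSAParams, RefinementParams, alignment_matches,
                               correct_tokens, edit_distance, lcs_length,
                               msa_score, ngram_overlap, refine,
                               select_candidate)
from figtext.lexicon import build_lexicon

from oracles import brute_alignment, brute_edit_distance, brute_lcs_length

words = st.text(alphabet=string.ascii_lowercase, max_size=12)
short_words = st.text(alphabet="abc", max_size=6)


# -- worked examples ---------------------------------------------------------

@pytest.mark.parametrize("w,c,expected", [
    ("antlsnze", "antisense", 3),   # two substitutions + one insertion
    ("antlsnze", "antiserum", 5),   # four substitutions + one insertion
    ("same", "same", 0),
    ("Radsap", "Rad52p", 2),        # frozen from the brute-force oracle
])
def test_edit_distance_examples(w, c, expected):
    assert edit_distance(w, c) == expected
    assert edit_distance(c, w) == expected


@pytest.mark.parametrize("w,c,expected", [
    ("antlsnze", "antisense", 6),   # LCS "antsne"
    ("antlsnze", "antiserum", 5),   # true LCS "antse" (oracle-verified)
    ("abc", "xyz", 0),
])
def test_lcs_examples(w, c, expected):
    assert lcs_length(w, c) == expected


@pytest.mark.parametrize("w,c,expected", [
    ("antlsnze", "antisense", 8),   # 6 matches, 2 mismatches, 1 gap
    ("antlsnze", "antiserum", 2),   # 4 matches, 4 mismatches, 1 gap
    ("abc", "abc", 6),
])
def test_msa_examples(w, c, expected):
    assert msa_score(w, c) == expected


def test_alignment_match_counts():
    assert alignment_matches("antlsnze", "antisense") == 6
    assert alignment_matches("antlsnze", "antiserum") == 4


# -- oracle equivalence ------------------------------------------------------

def test_edit_distance_matches_recursive_oracle(rng):
    for _ in range(200):
        a = "".join(rng.choice(list("abcd"), size=rng.integers(0, 7)))
        b = "".join(rng.choice(list("abcd"), size=rng.integers(0, 7)))
        assert edit_distance(a, b) == brute_edit_distance(a, b)


def test_lcs_matches_enumeration_oracle(rng):
    for _ in range(100):
        a = "".join(rng.choice(list("abc"), size=rng.integers(0, 8)))
        b = "".join(rng.choice(list("abc"), size=rng.integers(0, 8)))
        assert lcs_length(a, b) == brute_lcs_length(a, b)


def test_msa_matches_exhaustive_oracle(rng):
    params = MSAParams()
    for _ in range(60):
        a = "".join(rng.choice(list("abc"), size=rng.integers(0, 6)))
        b = "".join(rng.choice(list("abc"), size=rng.integers(0, 6)))
        score, matches = brute_alignment(a, b, params.match, params.mismatch,
                                         params.gap)
        assert msa_score(a, b, params) == score
        assert alignment_matches(a, b, params) == matches


def test_edit_distance_matches_edlib(rng):
    edlib = pytest.importorskip("edlib")
    for _ in range(300):
        a = "".join(rng.choice(list(string.ascii_lowercase), size=rng.integers(0, 13)))
        b = "".join(rng.choice(list(string.ascii_lowercase), size=rng.integers(0, 13)))
        if not a or not b:  # edlib rejects empty queries
            continue
        assert edit_distance(a, b) == edlib.align(a, b)["editDistance"]


def test_msa_matches_biopython_aligner(rng):
    Align = pytest.importorskip("Bio.Align")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    for _ in range(100):
        a = "".join(rng.choice(list("abcde"), size=rng.integers(1, 10)))
        b = "".join(rng.choice(list("abcde"), size=rng.integers(1, 10)))
        assert msa_score(a, b) == int(aligner.score(a, b))


# -- metric properties -------------------------------------------------------

@settings(max_examples=200, derandomize=True)
@given(words, words, words)
def test_edit_distance_metric_axioms(a, b, c):
    assert edit_distance(a, b) == edit_distance(b, a)
    assert (edit_distance(a, b) == 0) == (a == b)
    assert edit_distance(a, c) <= edit_distance(a, b) + edit_distance(b, c)


@settings(max_examples=300, derandomize=True)
@given(words, words)
def test_metric_inequalities(a, b):
    lcs = lcs_length(a, b)
    assert lcs <= min(len(a), len(b))
    assert edit_distance(a, b) >= max(len(a), len(b)) - lcs
    assert msa_score(a, b) <= 2 * lcs


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet=string.ascii_lowercase, min_size=1, max_size=12), words)
def test_ngram_overlap_range_and_self(a, b):
    t = ngram_overlap(a, b)
    assert 0.0 <= t <= 1.0
    assert ngram_overlap(a, a) == 1.0


# -- n-gram overlap and refinement ------------------------------------------

def test_ngram_overlap_hand_enumerated():
    # padded bigrams {_a,ab,bc,c_} vs {_a,ab,bd,d_} share 2 of 4
    assert ngram_overlap("abc", "abd") == pytest.approx(0.5)
    assert ngram_overlap("abc", "xyz") == 0.0


def test_padded_bigram_count_is_length_plus_one():
    # a length-L word padded with one boundary character per end yields L+1 bigrams
    from figtext.corrector import _padded_ngrams
    assert sum(_padded_ngrams("word", RefinementParams()).values()) == 5


def test_refinement_threshold_is_strict():
    accepted, t = refine("abc", "abd", RefinementParams(n=2, gamma=0.5))
    assert t == pytest.approx(0.5)
    assert not accepted  # T_overlap must strictly exceed gamma
    accepted, t = refine("abc", "abc", RefinementParams(gamma=0.99))
    assert accepted and t == 1.0
    accepted, _ = refine("abc", "xyz", RefinementParams(gamma=0.5))
    assert not accepted


# -- candidate selection -----------------------------------------------------

@pytest.fixture()
def small_lexicon():
    return build_lexicon(["antisense antiserum"], "caption")


def test_select_candidate_prefers_nearer_word(small_lexicon):
    assert select_candidate("antlsnze", small_lexicon, "ED") == "antisense"
    assert select_candidate("antlsnze", small_lexicon, "LCS") == "antisense"
    assert select_candidate("antlsnze", small_lexicon, "MSA") == "antisense"


def test_metric_choice_changes_the_winner():
    lex = build_lexicon(["Rad52p paraformaldehyde/saponin"], "caption")
    assert select_candidate("Radsap", lex, "ED") == "Rad52p"
    assert select_candidate("Radsap", lex, "LCS") == "paraformaldehyde/saponin"


def test_select_candidate_edge_cases(small_lexicon):
    with pytest.warns(UserWarning):
        empty = build_lexicon([""], "caption")
    assert select_candidate("word", empty, "ED") is None
    assert select_candidate("w", small_lexicon, "ED") is None  # length-1 query
    with pytest.raises(ValueError):
        select_candidate("word", small_lexicon, "fancy")


def test_tie_breaks_frequency_then_length_then_lexicographic():
    lex = build_lexicon(["aa aa ab"], "caption")  # aa twice -> higher frequency
    assert select_candidate("ac", lex, "ED") == "aa"
    lex2 = build_lexicon(["abcd abc"], "caption")  # equal distance 1 from "abcx"? no:
    # "abcx": ED to abc=1, abcd=1 -> shorter wins
    assert select_candidate("abcx", lex2, "ED") == "abc"
    lex3 = build_lexicon(["abd abf"], "caption")  # equal everything -> lexicographic
    assert select_candidate("abc", lex3, "ED") == "abd"


# -- token-stream correction -------------------------------------------------

def test_correct_tokens_pass_through_rules():
    lex = build_lexicon(["gene protein"], "caption")
    results = correct_tokens(["gene", "42", "genf"], lex, "ED")
    assert [r.final for r in results] == ["gene", "42", "gene"]
    assert results[0].accepted and results[0].candidate == "gene"
    assert results[1].candidate is None
    assert results[2].accepted and results[2].candidate == "gene"
    # invariant: accepted implies final == candidate
    for r in results:
        if r.accepted:
            assert r.final == r.candidate
        else:
            assert r.final == r.recognized


def test_refinement_protects_out_of_lexicon_words():
    lex = build_lexicon(["completely unrelated vocabulary"], "caption")
    plain = correct_tokens(["histone"], lex, "ED", refinement=False)
    refined = correct_tokens(["histone"], lex, "ED", refinement=True)
    assert plain[0].final != "histone"      # falsely corrected
    assert refined[0].final == "histone"    # preserved by the overlap test


def test_corruption_recovery_with_full_lexicon(rng):
    from figtext.ocr import OCRErrorModel, corrupt_word
    from figtext.synthetic import WORDLIST

    lex = build_lexicon([" ".join(WORDLIST)], "fulltext")
    words_drawn = [str(w) for w in rng.choice(WORDLIST, size=100, replace=True)]
    corrupted = [corrupt_word(w, OCRErrorModel(substitution_rate=0.15, seed=i))
                 for i, w in enumerate(words_drawn)]
    n_unchanged = sum(c == w for c, w in zip(corrupted, words_drawn))
    restored = {}
    for metric in ("ED", "LCS", "MSA"):
        res = correct_tokens(corrupted, lex, metric)
        restored[metric] = sum(r.final == w for r, w in zip(res, words_drawn))
    assert restored["ED"] >= 80
    assert restored["ED"] > n_unchanged        # correction beats no-correction
    assert restored["ED"] >= restored["LCS"]   # both fine-grained metrics beat
    assert restored["MSA"] >= restored["LCS"]  # subsequence counting
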