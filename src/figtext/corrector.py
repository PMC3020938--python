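"""Lexicon-based post-OCR text correction.

A recognized word ``w`` is compared with every candidate ``c_i`` in a
figure-specific lexicon under one of three word-similarity metrics:

* **ED** — unit-cost Levenshtein edit distance (lower is more similar);
* **LCS** — length of the longest common subsequence (higher is more similar);
* **MSA** — optimal scored global pairwise alignment (Needleman-Wunsch with a
  linear gap cost; defaults match +2, mismatch -1, gap -2; higher is more
  similar).

Because a correct out-of-lexicon word can be falsely "corrected" into a
lexicon token, an n-gram-overlap refinement step double-checks each proposed
correction: both words are decomposed into boundary-padded character n-grams,
and the correction is accepted only when the fraction

    T_overlap = (matched n-grams) / (n-grams of w)

exceeds a threshold gamma; otherwise the recognized word is kept.

All metric computations are case-insensitive (the lexicon stores and returns
original-case forms); the final evaluation elsewhere is case-sensitive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .lexicon import Lexicon

__all__ = [
    "MSAParams",
    "RefinementParams",
    "CorrectionResult",
    "edit_distance",
    "lcs_length",
    "msa_score",
    "alignment_matches",
    "select_candidate",
    "ngram_overlap",
    "refine",
    "correct_tokens",
    "METRICS",
]

METRICS = ("ED", "LCS", "MSA")


@dataclass(frozen=True)
class MSAParams:
    """Scores of the global pairwise alignment: positive match, non-positive
    mismatch and gap (linear gap cost, no affine opening penalty)."""

    match: int = 2
    mismatch: int = -1
    gap: int = -2

    def __post_init__(self) -> None:
        if not (self.match > 0 and self.mismatch <= 0 and self.gap <= 0):
            raise ValueError(f"require match > 0, mismatch <= 0, gap <= 0; got {self}")


@dataclass(frozen=True)
class RefinementParams:
    """Character n-gram order, acceptance threshold gamma, and the boundary
    pad character appended to both word ends before n-gram decomposition."""

    n: int = 2
    gamma: float = 0.5
    pad: str = " "

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n-gram order must be >= 1")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


@dataclass(frozen=True)
class CorrectionResult:
    """Outcome for one recognized token.

    ``accepted`` implies ``final == candidate``; otherwise the recognized
    word is passed through (``final == recognized``).
    """

    recognized: str
    candidate: str | None
    metric: str
    score: float
    t_overlap: float
    final: str
    accepted: bool


def edit_distance(w: str, c: str, casefold: bool = True) -> int:
    """Unit-cost Levenshtein distance between two words.

    Minimum number of single-character insertions, deletions and
    substitutions transforming one word into the other; symmetric and zero
    exactly for equal words (after optional case folding).
    """
    if casefold:
        w, c = w.casefold(), c.casefold()
    if len(w) < len(c):
        w, c = c, w
    prev = list(range(len(c) + 1))
    for i, wc in enumerate(w, 1):
        cur = [i]
        for j, cc in enumerate(c, 1):
            cur.append(min(prev[j] + 1,            # deletion
                           cur[j - 1] + 1,         # insertion
                           prev[j - 1] + (wc != cc)))  # substitution / match
        prev = cur
    return prev[-1]


def lcs_length(w: str, c: str, casefold: bool = True) -> int:
    """Length of the longest common subsequence (in-order, not necessarily
    contiguous)."""
    if casefold:
        w, c = w.casefold(), c.casefold()
    prev = [0] * (len(c) + 1)
    for wc in w:
        cur = [0]
        for j, cc in enumerate(c, 1):
            cur.append(prev[j - 1] + 1 if wc == cc else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def _nw_table(w: str, c: str, params: MSAParams) -> list[list[tuple[int, int]]]:
    """Needleman-Wunsch DP on (score, matches), lexicographically maximized,
    so the match count is the best achievable among optimal-score alignments."""
    nw, nc = len(w), len(c)
    table = [[(0, 0)] * (nc + 1) for _ in range(nw + 1)]
    for i in range(1, nw + 1):
        table[i][0] = (i * params.gap, 0)
    for j in range(1, nc + 1):
        table[0][j] = (j * params.gap, 0)
    for i in range(1, nw + 1):
        for j in range(1, nc + 1):
            hit = w[i - 1] == c[j - 1]
            ds, dm = table[i - 1][j - 1]
            diag = (ds + (params.match if hit else params.mismatch), dm + hit)
            us, um = table[i - 1][j]
            up = (us + params.gap, um)
            ls, lm = table[i][j - 1]
            left = (ls + params.gap, lm)
            table[i][j] = max(diag, up, left)
    return table


def msa_score(w: str, c: str, params: MSAParams = MSAParams(), casefold: bool = True) -> int:
    """Optimal global pairwise alignment score under match/mismatch/linear-gap
    scoring; identical length-L strings score ``L * match``."""
    if casefold:
        w, c = w.casefold(), c.casefold()
    return _nw_table(w, c, params)[len(w)][len(c)][0]


def alignment_matches(w: str, c: str, params: MSAParams = MSAParams(),
                      casefold: bool = True) -> int:
    """Number of identically matched character pairs in an optimal global
    alignment (the maximum over all optimal-score alignments)."""
    if casefold:
        w, c = w.casefold(), c.casefold()
    return _nw_table(w, c, params)[len(w)][len(c)][1]


def _padded_ngrams(word: str, params: RefinementParams) -> Counter:
    padded = params.pad + word + params.pad
    n = params.n
    if len(padded) < n:
        return Counter({padded: 1})
    return Counter(padded[i:i + n] for i in range(len(padded) - n + 1))


def ngram_overlap(w: str, c: str, params: RefinementParams = RefinementParams(),
                  casefold: bool = True) -> float:
    """T_overlap: the fraction of w's boundary-padded character n-grams that
    also occur in c's (multiset intersection / n-gram count of w)."""
    if not w:
        raise ValueError("recognized word must be non-empty")
    if casefold:
        w, c = w.casefold(), c.casefold()
    w_grams = _padded_ngrams(w, params)
    c_grams = _padded_ngrams(c, params) if c else Counter()
    matched = sum((w_grams & c_grams).values())
    return matched / sum(w_grams.values())


def select_candidate(w: str, lex: Lexicon, metric: str = "ED",
                     params: MSAParams = MSAParams()) -> str | None:
    """Best lexicon candidate for ``w`` under a similarity metric.

    ED is minimized; LCS and MSA scores are maximized.  Ties break toward the
    higher-frequency, then shorter, then lexicographically smaller candidate.
    Returns ``None`` when the lexicon offers no candidate or ``w`` is a
    single character.
    """
    metric = metric.upper()
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if len(w) <= 1:
        return None
    best: tuple | None = None
    best_cand: str | None = None
    for cand in lex.candidates():
        if metric == "ED":
            score = -edit_distance(w, cand)
        elif metric == "LCS":
            score = lcs_length(w, cand)
        else:
            score = msa_score(w, cand, params)
        key = (score, lex.frequencies[cand], -len(cand),
               [-ord(ch) for ch in cand.casefold()])
        if best is None or key > best:
            best = key
            best_cand = cand
    return best_cand


def _metric_score(w: str, cand: str, metric: str, params: MSAParams) -> float:
    if metric == "ED":
        return float(edit_distance(w, cand))
    if metric == "LCS":
        return float(lcs_length(w, cand))
    return float(msa_score(w, cand, params))


def refine(w: str, candidate: str,
           params: RefinementParams = RefinementParams()) -> tuple[bool, float]:
    """Accept the proposed correction only when T_overlap strictly exceeds
    gamma; returns ``(accepted, t_overlap)``."""
    t = ngram_overlap(w, candidate, params)
    return t > params.gamma, t


def correct_tokens(tokens, lex: Lexicon, metric: str = "ED",
                   refinement: bool = False,
                   msa_params: MSAParams = MSAParams(),
                   refinement_params: RefinementParams = RefinementParams()) -> list[CorrectionResult]:
    """Correct a token stream against a lexicon.

    Tokens already in the lexicon, and tokens with no letters at all
    (numbers, bare symbols), pass through unchanged.  With ``refinement``
    off, the best candidate always replaces the token (when one exists); with
    it on, the n-gram-overlap test decides between candidate and original.
    Accepts ``RecognizedToken``-like objects (with a ``.text``) or strings.
    """
    metric = metric.upper()
    results: list[CorrectionResult] = []
    for tok in tokens:
        w = tok.text if hasattr(tok, "text") else str(tok)
        if not w or not any(ch.isalpha() for ch in w):
            results.append(CorrectionResult(w, None, metric, 0.0, 0.0, w, False))
            continue
        if w in lex:
            results.append(CorrectionResult(w, w, metric, 0.0, 1.0, w, True))
            continue
        cand = select_candidate(w, lex, metric, msa_params)
        if cand is None:
            results.append(CorrectionResult(w, None, metric, 0.0, 0.0, w, False))
            continue
        score = _metric_score(w, cand, metric, msa_params)
        if refinement:
            accepted, t = refine(w, cand, refinement_params)
        else:
            accepted, t = True, ngram_overlap(w, cand, refinement_params)
        results.append(CorrectionResult(
            recognized=w, candidate=cand, metric=metric, score=score,
            t_overlap=t, final=cand if accepted else w, accepted=accepted))
    return results
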