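"""Strict evaluation of extracted figure text.

Word-level scoring ignores tokens that carry no letters (numbers and bare
symbols) and then requires exact, case-sensitive, character-for-character
equality with the transcribed gold text.  Counts follow the four counting
variables: recognized words N_R, correct recognized words N_C, gold figure
texts N_F, and retrieved gold texts N_T; precision = N_C/N_R, recall =
N_T/N_F, F1 their harmonic mean.  Matching is one-to-one on multisets, so a
single correct extraction cannot satisfy two identical gold tokens (and
therefore N_C == N_T).

Character accuracy is scored per (extracted, gold) pair as the number of
identically matched characters in an optimal global character alignment
divided by the gold length, aggregated overall and per gold word length.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from .corrector import MSAParams, alignment_matches

__all__ = ["EvalCounts", "normalize_for_eval", "text_metrics",
           "character_accuracy", "word_accuracy_by_length"]


@dataclass(frozen=True)
class EvalCounts:
    n_recognized: int          # N_R
    n_correct_recognized: int  # N_C
    n_gold: int                # N_F
    n_retrieved_gold: int      # N_T


def normalize_for_eval(tokens: list[str]) -> list[str]:
    """Drop tokens containing no letters; keep the rest verbatim."""
    return [t for t in tokens if any(ch.isalpha() for ch in t)]


def text_metrics(extracted: list[str], gold: list[str]
                 ) -> tuple[EvalCounts, float, float, float]:
    """Strict word-level precision/recall/F1 with one-to-one multiset
    matching; zero denominators yield 0 by convention."""
    matched = sum((Counter(extracted) & Counter(gold)).values())
    counts = EvalCounts(
        n_recognized=len(extracted),
        n_correct_recognized=matched,
        n_gold=len(gold),
        n_retrieved_gold=matched,
    )
    p = counts.n_correct_recognized / counts.n_recognized if counts.n_recognized else 0.0
    r = counts.n_retrieved_gold / counts.n_gold if counts.n_gold else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return counts, p, r, f1


def character_accuracy(pairs: list[tuple[str, str]],
                       params: MSAParams = MSAParams()
                       ) -> tuple[float, dict[int, float]]:
    """Character accuracy overall and bucketed by gold word length.

    Each pair contributes (matched characters in the optimal case-sensitive
    character alignment) / len(gold); unpaired gold words are passed as
    ``("", gold)`` and contribute zero.  Aggregation is per gold character
    (total matched / total gold length).
    """
    matched_total = 0
    gold_total = 0
    by_len: dict[int, list[int]] = defaultdict(lambda: [0, 0])
    for ext, gold in pairs:
        if not gold:
            raise ValueError("gold word must be non-empty")
        m = alignment_matches(ext, gold, params, casefold=False) if ext else 0
        matched_total += m
        gold_total += len(gold)
        bucket = by_len[len(gold)]
        bucket[0] += m
        bucket[1] += len(gold)
    overall = matched_total / gold_total if gold_total else 0.0
    return overall, {k: m / g for k, (m, g) in sorted(by_len.items())}


def word_accuracy_by_length(pairs: list[tuple[str, str]]) -> dict[int, float]:
    """Exact-match indicator averaged per gold-length bucket."""
    by_len: dict[int, list[int]] = defaultdict(lambda: [0, 0])
    for ext, gold in pairs:
        bucket = by_len[len(gold)]
        bucket[0] += int(ext == gold)
        bucket[1] += 1
    return {k: hit / n for k, (hit, n) in sorted(by_len.items())}
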