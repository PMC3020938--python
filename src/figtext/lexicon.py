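"""Figure-specific lexicons for post-OCR correction.

Figure text usually also appears in the figure's surrounding context, so four
lexicons are built from plain-text sources: the figure caption, the
figure-associated article text, their union, and the article full text.
Candidate lookup is case-insensitive (the stored original-case form is what a
correction returns), and token frequencies are kept to break ties between
equally similar candidates.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

__all__ = ["SOURCE_KINDS", "Lexicon", "tokenize", "build_lexicon",
           "union_lexicon", "load_lexicon", "save_lexicon"]

SOURCE_KINDS = ("caption", "associated", "caption+associated", "fulltext")

#: punctuation stripped from token edges; internal '-', '/', '+' survive so
#: linked terms like "TBP-TFB-RNAP" stay intact.
_EDGE_PUNCT = "\"'`.,;:!?()[]{}<>«»“”‘’|\\^~*&#@%$=+-–—_/"


def tokenize(text: str) -> list[str]:
    """Split text into word tokens.

    Whitespace-delimited; leading/trailing punctuation is stripped (internal
    hyphens, slashes and plus signs are preserved); tokens without any letter
    (bare numbers and symbols) are dropped.
    """
    out = []
    for raw in text.split():
        tok = raw.strip(_EDGE_PUNCT)
        if tok and any(ch.isalpha() for ch in tok):
            out.append(tok)
    return out


@dataclass
class Lexicon:
    """A deduplicated token collection from one figure-specific source."""

    source_kind: str = "caption"
    frequencies: Counter = field(default_factory=Counter)
    # case-folded form -> stored original-case form (most frequent wins)
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.frequencies and not self._index:
            self._rebuild_index()

    def _rebuild_index(self) -> None:
        self._index = {}
        for tok in sorted(self.frequencies, key=lambda t: (-self.frequencies[t], t)):
            self._index.setdefault(tok.casefold(), tok)

    @property
    def tokens(self) -> set:
        return set(self.frequencies)

    def __len__(self) -> int:
        return len(self.frequencies)

    def __contains__(self, word: str) -> bool:
        return word.casefold() in self._index

    def add(self, token: str, count: int = 1) -> None:
        self.frequencies[token] += count
        stored = self._index.get(token.casefold())
        if stored is None or self.frequencies[token] > self.frequencies.get(stored, 0):
            self._index[token.casefold()] = token

    def lookup(self, word: str) -> str | None:
        """Stored original-case form for a case-insensitive match, or None."""
        return self._index.get(word.casefold())

    def frequency(self, word: str) -> int:
        stored = self.lookup(word)
        return self.frequencies[stored] if stored is not None else 0

    def candidates(self) -> list[str]:
        """Correction candidates: every stored token of length > 1 (length-1
        tokens such as panel labels are never offered as corrections)."""
        return [t for t in self.frequencies if len(t) > 1]


def build_lexicon(sources: list[str], kind: str = "caption") -> Lexicon:
    """Build a lexicon from raw text documents of one source kind."""
    if kind not in SOURCE_KINDS:
        raise ValueError(f"unknown lexicon kind {kind!r}; expected one of {SOURCE_KINDS}")
    lex = Lexicon(source_kind=kind)
    any_text = False
    for text in sources:
        if text.strip():
            any_text = True
        for tok in tokenize(text):
            lex.add(tok)
    if not any_text:
        warnings.warn(f"building {kind!r} lexicon from empty sources", stacklevel=2)
    return lex


def union_lexicon(caption: Lexicon, associated: Lexicon) -> Lexicon:
    """The caption+associated lexicon is the union of the two builds, with
    accumulated frequencies."""
    lex = Lexicon(source_kind="caption+associated")
    for src in (caption, associated):
        for tok, cnt in src.frequencies.items():
            lex.add(tok, cnt)
    return lex


def load_lexicon(path, kind: str = "caption") -> Lexicon:
    """Read a word-per-line lexicon file (optional tab-separated count)."""
    lex = Lexicon(source_kind=kind)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            tok, _, cnt = line.partition("\t")
            lex.add(tok, int(cnt) if cnt else 1)
    return lex


def save_lexicon(lex: Lexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tok in sorted(lex.frequencies):
            fh.write(f"{tok}\t{lex.frequencies[tok]}\n")
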