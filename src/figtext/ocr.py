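"""Pluggable character recognition over localized regions.

The recognition engine is deliberately a plug-in: any external OCR can be
registered by name, and the repository itself ships two engines that make the
surrounding pipeline fully testable without one:

* ``fixture`` — a deterministic glyph-atlas template matcher.  It renders a
  reference atlas with the same font faces the synthetic generator uses,
  segments a region into glyph clusters (8-connected components grouped by
  horizontal overlap, so an i-dot joins its stem), and assigns each cluster
  the atlas character with the closest scale-normalized shape.  On clean
  regions it reads back exactly the rendered string — the testing baseline.
* ``noisy-fixture`` — the fixture engine composed with a seeded OCR-error
  channel (``corrupt_word``) that applies per-character substitutions (biased
  toward classic OCR confusions such as l/i, e/c, s/z, o/0), deletions and
  insertions, reproducibly per (seed, word).

Requesting an unavailable engine raises ``BackendMissingError`` — never a
silent empty result.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage as ndi
from skimage import filters, measure

from ._fontutil import load_font
from .imageprep import as_gray_image

__all__ = [
    "RecognizedToken",
    "OCRErrorModel",
    "BackendMissingError",
    "FixtureRecognizer",
    "NoisyFixtureRecognizer",
    "register_engine",
    "get_engine",
    "available_engines",
    "recognize",
    "corrupt_word",
]

#: classic OCR character confusions; most OCR errors hit lowercase letters.
DEFAULT_CONFUSIONS = {
    "l": "i", "i": "l", "e": "c", "c": "e", "s": "z", "z": "s",
    "5": "s", "0": "o", "o": "0", "m": "rn",
}


class BackendMissingError(RuntimeError):
    """An OCR engine was requested that is not available."""


@dataclass(frozen=True)
class RecognizedToken:
    """One whitespace-delimited token read from a region."""

    text: str
    region_id: int = 0
    confidence: float | None = None


@dataclass(frozen=True)
class OCRErrorModel:
    """Seeded per-character error channel emulating OCR noise."""

    substitution_rate: float = 0.0
    deletion_rate: float = 0.0
    insertion_rate: float = 0.0
    confusion_pairs: tuple = tuple(DEFAULT_CONFUSIONS.items())
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.deletion_rate, self.insertion_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")
        if self.substitution_rate + self.deletion_rate > 1.0:
            raise ValueError("substitution_rate + deletion_rate must be <= 1")


_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def corrupt_word(word: str, model: OCRErrorModel) -> str:
    """Apply the error channel to one word, reproducibly.

    The RNG is seeded from ``(model.seed, word)`` so the corruption of a word
    does not depend on call order.  Per character one event is drawn
    (substitute / delete / keep); substitutions use the confusion table when
    the character has an entry, otherwise a random letter.  After every
    position an insertion of a random letter may occur.
    """
    rng = np.random.default_rng((np.uint64(model.seed) << np.uint64(32))
                                + np.uint64(zlib.crc32(word.encode("utf-8"))))
    confusions = dict(model.confusion_pairs)
    out: list[str] = []

    def maybe_insert() -> None:
        if model.insertion_rate and rng.random() < model.insertion_rate:
            out.append(_ALPHABET[rng.integers(len(_ALPHABET))])

    maybe_insert()
    for ch in word:
        u = rng.random()
        if u < model.substitution_rate:
            sub = confusions.get(ch)
            if sub is None:
                sub = _ALPHABET[rng.integers(len(_ALPHABET))]
                if sub == ch:  # force a real substitution
                    sub = _ALPHABET[(_ALPHABET.index(sub) + 1) % len(_ALPHABET)] \
                        if ch in _ALPHABET else "x"
            out.append(sub)
        elif u < model.substitution_rate + model.deletion_rate:
            pass
        else:
            out.append(ch)
        maybe_insert()
    return "".join(out)


# ---------------------------------------------------------------------------
# fixture engine: glyph-atlas template matching
# ---------------------------------------------------------------------------

_NORM = 24          # glyph shapes are compared on a _NORM x _NORM canvas
_ATLAS_SIZE = 48    # reference rendering size for atlas glyphs


def _normalize_glyph(mask: np.ndarray) -> np.ndarray:
    """Tight-crop a binary glyph mask and scale it (aspect preserved) onto a
    fixed square canvas for shape comparison."""
    ys, xs = np.nonzero(mask)
    crop = mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1].astype(np.uint8) * 255
    h, w = crop.shape
    scale = (_NORM - 2) / max(h, w)
    nh, nw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    im = Image.fromarray(crop, mode="L").resize((nw, nh), Image.BILINEAR)
    canvas = np.zeros((_NORM, _NORM), dtype=float)
    y0 = (_NORM - nh) // 2
    x0 = (_NORM - nw) // 2
    canvas[y0:y0 + nh, x0:x0 + nw] = np.asarray(im, dtype=float) / 255.0
    # slight blur makes the comparison tolerant to 1-px boundary shifts from
    # anti-aliasing and contrast stretching
    return ndi.gaussian_filter(canvas, sigma=1.0)


class FixtureRecognizer:
    """Deterministic recognizer backed by its own rendered glyph atlas.

    Parameters
    ----------
    charset:
        Characters the atlas knows.  The default covers the synthetic
        generator's vocabulary (lowercase letters); extend it when rendering
        other strings.
    faces:
        Font faces to include in the atlas (the generator's faces).
    space_gap_factor:
        A horizontal gap wider than this fraction of the median glyph height
        splits two tokens.
    """

    name = "fixture"

    #: character pairs that physically touch in common faces and therefore
    #: appear as a single connected cluster; stored as multi-char templates
    LIGATURES = ("ff", "fi", "fl", "tt", "rt")

    def __init__(self, charset: str = _ALPHABET, faces: tuple[str, ...] = ("sans", "serif"),
                 space_gap_factor: float = 0.45):
        self.charset = charset
        self.space_gap_factor = space_gap_factor
        self._atlas: list[tuple[str, np.ndarray]] = []
        for face in faces:
            font = load_font(face, _ATLAS_SIZE)
            for text in list(charset) + list(self.LIGATURES):
                canvas = Image.new("L", (4 * _ATLAS_SIZE, 3 * _ATLAS_SIZE), 255)
                ImageDraw.Draw(canvas).text((_ATLAS_SIZE, _ATLAS_SIZE), text, fill=0, font=font)
                arr = np.asarray(canvas)
                mask = arr < 128
                if mask.any():
                    self._atlas.append((text, _normalize_glyph(mask)))

    # -- segmentation ------------------------------------------------------

    @staticmethod
    def _foreground(region_image: np.ndarray) -> np.ndarray:
        img = as_gray_image(region_image)
        if img.min() == img.max():
            return np.zeros_like(img, bool)
        t = filters.threshold_otsu(img)
        mask = img < t
        # dark-on-bright convention: if most pixels ended up foreground the
        # region is essentially blank shading, not text
        if mask.mean() > 0.5:
            return np.zeros_like(img, bool)
        return mask

    def _clusters(self, mask: np.ndarray) -> list[tuple[int, int, np.ndarray]]:
        """Group components into glyph clusters; a component joins an earlier
        one only when their x-ranges overlap substantially (an i/j dot over
        its stem), so kerning overlap between neighbors does not fuse them.
        Returns (x0, x1, cluster mask) in left-to-right order."""
        labels = measure.label(mask, connectivity=2)
        props = measure.regionprops(labels)
        if not props:
            return []
        spans = sorted(
            ((p.bbox[1], p.bbox[3], p.label) for p in props), key=lambda s: (s[0], s[1]))
        merged: list[list] = []
        for x0, x1, lab in spans:
            if merged:
                px0, px1 = merged[-1][0], merged[-1][1]
                overlap = min(px1, x1) - max(px0, x0)
                if overlap >= 0.6 * min(x1 - x0, px1 - px0):
                    merged[-1][1] = max(px1, x1)
                    merged[-1][2].append(lab)
                    continue
            merged.append([x0, x1, [lab]])
        out = []
        for x0, x1, labs in merged:
            m = np.isin(labels, labs)
            out.append((x0, x1, m))
        return out

    def recognize_text(self, region_image: np.ndarray) -> str:
        """Read a region into a string (tokens separated by single spaces)."""
        mask = self._foreground(region_image)
        if not mask.any():
            return ""
        clusters = self._clusters(mask)
        heights = []
        for _, _, m in clusters:
            ys = np.nonzero(m.any(axis=1))[0]
            heights.append(ys.max() - ys.min() + 1)
        ref_h = float(np.median(heights))
        pieces: list[str] = []
        prev_x1: int | None = None
        for (x0, x1, m) in clusters:
            if prev_x1 is not None and (x0 - prev_x1) > self.space_gap_factor * ref_h:
                pieces.append(" ")
            pieces.append(self._classify(m))
            prev_x1 = x1
        return "".join(pieces)

    def _best_template(self, glyph_mask: np.ndarray) -> tuple[str, float]:
        shape = _normalize_glyph(glyph_mask)
        best_ch, best_err = "?", np.inf
        for ch, tmpl in self._atlas:
            err = float(np.mean((shape - tmpl) ** 2))
            if err < best_err:
                best_ch, best_err = ch, err
        return best_ch, best_err

    # a clean single glyph typically matches its template well below this;
    # fused glyph pairs (e.g. 'ff', 'rt' at small sizes) match far worse
    _SPLIT_ERR = 0.06

    def _classify(self, glyph_mask: np.ndarray, depth: int = 0) -> str:
        ch, err = self._best_template(glyph_mask)
        if err <= self._SPLIT_ERR or depth >= 2:
            return ch
        split = self._try_split(glyph_mask, depth)
        if split is not None and split[1] < err:
            return split[0]
        return ch

    def _try_split(self, glyph_mask: np.ndarray, depth: int) -> tuple[str, float] | None:
        """Attempt to cut a poorly matching cluster of touching characters.

        Candidate cut columns are sampled across the interior; the cut whose
        two halves jointly match the atlas best wins.  Returns (text, mean
        error) or None when no cut produces two non-empty halves."""
        ys, xs = np.nonzero(glyph_mask)
        crop = glyph_mask[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
        h, w = crop.shape
        if w < 8 or w < 0.6 * h:
            return None
        lo, hi = max(2, int(0.2 * w)), min(w - 2, int(0.8 * w))
        if hi <= lo:
            return None
        best: tuple[str, float] | None = None
        for cut in range(lo, hi):
            left, right = crop[:, :cut], crop[:, cut + 1:]
            if not left.any() or not right.any():
                continue
            parts, errs = [], []
            for part in (left, right):
                ch, err = self._best_template(part)
                if err > self._SPLIT_ERR and depth + 1 < 2:
                    sub = self._try_split(part, depth + 1)
                    if sub is not None and sub[1] < err:
                        parts.append(sub[0]); errs.append(sub[1]); continue
                parts.append(ch); errs.append(err)
            cand = ("".join(parts), float(np.mean(errs)))
            if best is None or cand[1] < best[1]:
                best = cand
        return best

    def recognize(self, region_image: np.ndarray, region_id: int = 0) -> list[RecognizedToken]:
        text = self.recognize_text(region_image)
        return [RecognizedToken(tok, region_id) for tok in text.split()]


class NoisyFixtureRecognizer(FixtureRecognizer):
    """Fixture engine whose output tokens pass through an OCR-error channel."""

    name = "noisy-fixture"

    def __init__(self, error_model: OCRErrorModel = OCRErrorModel(substitution_rate=0.15, seed=0),
                 **kwargs):
        super().__init__(**kwargs)
        self.error_model = error_model

    def recognize(self, region_image: np.ndarray, region_id: int = 0) -> list[RecognizedToken]:
        clean = super().recognize(region_image, region_id)
        return [RecognizedToken(corrupt_word(t.text, self.error_model), t.region_id)
                for t in clean]


# ---------------------------------------------------------------------------
# engine registry
# ---------------------------------------------------------------------------

_ENGINES: dict[str, type] = {}


def register_engine(name: str, factory) -> None:
    """Register an OCR engine factory under a config name."""
    _ENGINES[name] = factory


def available_engines() -> list[str]:
    return sorted(_ENGINES)


def get_engine(name: str, **kwargs):
    """Instantiate a registered engine; unknown names raise
    ``BackendMissingError`` (never a silent fallback)."""
    try:
        factory = _ENGINES[name]
    except KeyError:
        raise BackendMissingError(
            f"OCR engine {name!r} is not available; registered engines: "
            f"{available_engines()}") from None
    return factory(**kwargs)


register_engine("fixture", FixtureRecognizer)
register_engine("noisy-fixture", NoisyFixtureRecognizer)


def recognize(region_image: np.ndarray, engine, region_id: int = 0) -> list[RecognizedToken]:
    """Recognize tokens in an (up-sampled) localized region.

    ``engine`` is an engine instance or a registered engine name; tokens are
    whitespace-split, left to right.
    """
    if isinstance(engine, str):
        engine = get_engine(engine)
    return engine.recognize(region_image, region_id=region_id)
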