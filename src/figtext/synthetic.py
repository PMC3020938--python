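"""Synthetic figure generator: rendered text with exact ground truth.

Real figure corpora cannot be redistributed, so every stage of the pipeline
is exercised on figures rendered here: each figure carries known text
strings, exact glyph-tight bounding boxes, and per-figure caption-like and
associated-text-like files with a configurable fraction of the rendered
words (so lexicon-coverage effects are reproducible).  Degradation modes
reproduce the classic failure taxonomy — background complexity, thick
strokes, low gray-level contrast, and small font sizes (via the spec's font
size) — each seeded and deterministic.

Everything is reproducible from ``(profile, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage as ndi

from ._fontutil import load_font
from .imageprep import as_gray_image

__all__ = [
    "SpecError",
    "TextItem",
    "SyntheticFigureSpec",
    "WORDLIST",
    "DISTRACTORS",
    "render_figure",
    "degrade",
    "make_dataset",
    "load_gold",
]


class SpecError(ValueError):
    """A figure spec violates its invariants (e.g. overlapping items)."""


#: Generator vocabulary: lowercase tokens in the style of figure labels
#: (gene/protein-ish names, assay words).  Lowercase keeps the fixture
#: recognizer's atlas unambiguous.
WORDLIST = [
    "actin", "agarose", "aliquot", "amplicon", "anneal", "antibody",
    "antigen", "antisense", "antiserum", "apoptosis", "assay", "band",
    "binding", "blot", "buffer", "candidate", "cell", "chromatin", "clone",
    "codon", "colony", "complex", "control", "culture", "cytoplasm",
    "daltons", "deletion", "dimer", "domain", "dorsal", "duplex", "elution",
    "embryo", "enzyme", "epitope", "exon", "expression", "fraction",
    "fusion", "gel", "gene", "genome", "gradient", "growth", "helix",
    "histone", "hybrid", "input", "insert", "intron", "kinase", "lane",
    "ligand", "ligase", "lysate", "marker", "membrane", "merge", "mock",
    "motif", "mutant", "native", "nuclear", "operon", "pellet", "peptide",
    "phase", "plasmid", "polymer", "primer", "probe", "promoter", "protein",
    "pulse", "purified", "reporter", "residue", "ribosome", "sample",
    "sense", "serum", "signal", "splice", "strand", "subunit", "substrate",
    "template", "tissue", "transcript", "treated", "trimer", "tubulin",
    "untreated", "upstream", "vector", "vesicle", "wash", "western",
]

#: Words reserved for lexicon noise; never rendered into figures.
DISTRACTORS = [
    "abstract", "analysis", "approach", "article", "author", "baseline",
    "chapter", "citation", "compare", "dataset", "discussion", "evaluate",
    "figure", "journal", "method", "panel", "reference", "result",
    "section", "summary", "table", "version",
]


@dataclass(frozen=True)
class TextItem:
    """One rendered text string on the canvas."""

    text: str
    position: tuple[int, int]          # top-left drawing anchor (x, y)
    font_size: int = 18
    face: str = "sans"                 # 'sans' | 'serif'
    polarity: str = "dark"             # dark text on bright bg, or 'bright'
    stroke: int = 0                    # extra stroke width in px
    contrast: float = 1.0              # fraction of the full fg/bg gray gap


@dataclass(frozen=True)
class SyntheticFigureSpec:
    width: int = 480
    height: int = 360
    background: str = "plain"          # plain | gradient | texture | lineart
    bg_level: int = 235
    items: tuple[TextItem, ...] = ()
    seed: int = 0


def _render_item_alpha(item: TextItem, size: tuple[int, int]) -> np.ndarray:
    """Anti-aliased coverage of one item's glyphs in [0, 1]."""
    layer = Image.new("L", size, 0)
    font = load_font(item.face, item.font_size)
    ImageDraw.Draw(layer).text(item.position, item.text, fill=255, font=font,
                               stroke_width=item.stroke, stroke_fill=255)
    return np.asarray(layer, dtype=float) / 255.0


def _background(spec: SyntheticFigureSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    bg = np.full((h, w), float(spec.bg_level))
    if spec.background == "plain":
        pass
    elif spec.background == "gradient":
        ramp = np.linspace(-18, 18, w)[None, :]
        bg = bg + ramp
    elif spec.background == "texture":
        noise = ndi.gaussian_filter(rng.normal(0, 1, (h, w)), sigma=6)
        bg = bg + 12 * noise / max(1e-9, np.abs(noise).max())
    elif spec.background == "lineart":
        im = Image.fromarray(np.clip(bg, 0, 255).astype(np.uint8), "L")
        draw = ImageDraw.Draw(im)
        for _ in range(6):
            x0, x1 = rng.integers(0, w, 2)
            y0, y1 = rng.integers(0, h, 2)
            draw.line((int(x0), int(y0), int(x1), int(y1)), fill=90, width=1)
        bg = np.asarray(im, dtype=float)
    else:
        raise SpecError(f"unknown background mode {spec.background!r}")
    return np.clip(bg, 0, 255)


def render_figure(spec: SyntheticFigureSpec) -> tuple[np.ndarray, list[dict]]:
    """Render a spec into a gray image plus its ground-truth annotation.

    The annotation is a JSON-ready list of ``{id, x, y, w, h, text}`` with
    glyph-tight boxes.  Deterministic for a given spec (the seed drives the
    background noise).  Overlapping item boxes raise ``SpecError``.
    """
    canvas = _background(spec)
    size = (spec.width, spec.height)
    gold: list[dict] = []
    boxes: list[tuple[int, int, int, int]] = []
    for i, item in enumerate(spec.items):
        alpha = _render_item_alpha(item, size)
        solid = alpha >= 0.5
        if not solid.any():
            raise SpecError(f"item {i} ({item.text!r}) rendered no pixels")
        ys, xs = np.nonzero(solid)
        box = (int(xs.min()), int(ys.min()),
               int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))
        if box[0] < 0 or box[1] < 0 or box[0] + box[2] > spec.width \
                or box[1] + box[3] > spec.height:
            raise SpecError(f"item {i} ({item.text!r}) leaves the canvas")
        for other in boxes:
            if (box[0] < other[0] + other[2] and other[0] < box[0] + box[2]
                    and box[1] < other[1] + other[3] and other[1] < box[1] + box[3]):
                raise SpecError(f"item {i} ({item.text!r}) overlaps another item")
        boxes.append(box)
        if item.polarity == "dark":
            fg = spec.bg_level - item.contrast * (spec.bg_level - 5)
        else:
            fg = spec.bg_level + item.contrast * (250 - spec.bg_level)
        canvas = canvas * (1 - alpha) + fg * alpha
        gold.append({"id": i, "x": box[0], "y": box[1], "w": box[2], "h": box[3],
                     "text": item.text})
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8), gold


def degrade(img: np.ndarray, mode: str, strength: float, seed: int = 0) -> np.ndarray:
    """Apply one seeded degradation mode at a given strength in [0, 1].

    ``low_contrast`` compresses the gray gap between text and background;
    ``thick_stroke`` dilates dark glyph strokes (gray-level erosion);
    ``complexity`` composites line-art clutter.  Strength 0 is the identity.
    Small font size is a property of the figure spec, not a post filter.
    """
    img = as_gray_image(img)
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    if strength == 0.0:
        return img.copy()
    if mode == "low_contrast":
        bg = float(np.median(img))
        out = bg + (img.astype(float) - bg) * (1.0 - strength)
    elif mode == "thick_stroke":
        radius = int(round(2 * strength))
        if radius == 0:
            return img.copy()
        out = ndi.grey_erosion(img, size=2 * radius + 1)
    elif mode == "complexity":
        rng = np.random.default_rng(seed)
        im = Image.fromarray(img, "L")
        draw = ImageDraw.Draw(im)
        h, w = img.shape
        for _ in range(int(round(2 + 10 * strength))):
            x0, x1 = rng.integers(0, w, 2)
            y0, y1 = rng.integers(0, h, 2)
            draw.line((int(x0), int(y0), int(x1), int(y1)), fill=70, width=1)
        out = np.asarray(im, dtype=float)
    else:
        raise SpecError(f"unknown degradation mode {mode!r}")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

PROFILES = {
    # near-perfectly solvable: plain bright background, >= 14 px fonts, full
    # contrast — separates algorithm correctness from corpus difficulty
    "easy": dict(background=("plain",), font_sizes=(16, 18, 20, 22, 24),
                 faces=("sans",), contrast=(1.0,), items=(4, 7), stroke=(0,)),
    # stressed conditions from the error taxonomy: busier backgrounds,
    # smaller fonts, reduced contrast
    "hard": dict(background=("plain", "gradient", "texture", "lineart"),
                 font_sizes=(10, 12, 14, 16), faces=("sans", "serif"),
                 contrast=(0.45, 0.7, 1.0), items=(5, 9), stroke=(0, 1)),
}


def _spec_for_figure(profile: dict, rng: np.random.Generator, seed: int,
                     width: int = 480, height: int = 360) -> SyntheticFigureSpec:
    n_items = int(rng.integers(profile["items"][0], profile["items"][1] + 1))
    words = list(rng.choice(WORDLIST, size=n_items, replace=False))
    items = []
    y = 14
    for word in words:
        fs = int(rng.choice(profile["font_sizes"]))
        face = str(rng.choice(profile["faces"]))
        x = int(rng.integers(12, max(13, width - 12 - int(0.75 * fs * len(word)))))
        items.append(TextItem(text=str(word), position=(x, y), font_size=fs,
                              face=face,
                              contrast=float(rng.choice(profile["contrast"])),
                              stroke=int(rng.choice(profile["stroke"]))))
        y += int(2.2 * fs)
    return SyntheticFigureSpec(
        width=width, height=height,
        background=str(rng.choice(profile["background"])),
        items=tuple(items), seed=seed)


def make_dataset(n_figures: int, profile: str = "easy", seed: int = 0,
                 out_dir: str | Path | None = None,
                 coverage: float = 0.35) -> dict:
    """Generate a dataset of figures, gold annotations and lexicon sources.

    Each figure gets a caption-like and an associated-text-like file holding
    ``coverage`` of its rendered words (sampled without replacement) mixed
    with distractor words, so lexicon-coverage effects are reproducible.
    When ``out_dir`` is given the layout is ``images/NNN.png``,
    ``gold/NNN.json``, ``lexicons/NNN.caption.txt``,
    ``lexicons/NNN.assoc.txt`` and ``manifest.json``; the returned manifest
    also carries every figure in memory.
    """
    if n_figures < 1:
        raise ValueError("n_figures must be >= 1")
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {sorted(PROFILES)}")
    rng = np.random.default_rng(seed)
    prof = PROFILES[profile]
    figures = []
    for k in range(n_figures):
        fig_seed = int(rng.integers(0, 2**31 - 1))
        spec = _spec_for_figure(prof, rng, fig_seed)
        img, gold = render_figure(spec)
        words = [g["text"] for g in gold]

        def source_text(local_rng: np.random.Generator) -> str:
            n_cov = int(round(coverage * len(words)))
            covered = list(local_rng.choice(words, size=n_cov, replace=False)) if n_cov else []
            n_noise = int(local_rng.integers(6, 12))
            noise = list(local_rng.choice(DISTRACTORS, size=min(n_noise, len(DISTRACTORS)),
                                          replace=False))
            mixed = covered + noise
            local_rng.shuffle(mixed)
            return " ".join(str(t) for t in mixed)

        figures.append({
            "name": f"{k:03d}",
            "spec": spec,
            "image": img,
            "gold": gold,
            "caption": source_text(np.random.default_rng(fig_seed + 1)),
            "assoc": source_text(np.random.default_rng(fig_seed + 2)),
        })

    manifest = {"profile": profile, "seed": seed, "n_figures": n_figures,
                "coverage": coverage, "figures": figures}

    if out_dir is not None:
        out = Path(out_dir)
        for sub in ("images", "gold", "lexicons"):
            (out / sub).mkdir(parents=True, exist_ok=True)
        index = []
        for fig in figures:
            name = fig["name"]
            Image.fromarray(fig["image"], "L").save(out / "images" / f"{name}.png")
            with open(out / "gold" / f"{name}.json", "w", encoding="utf-8") as fh:
                json.dump(fig["gold"], fh, indent=2)
            (out / "lexicons" / f"{name}.caption.txt").write_text(
                fig["caption"] + "\n", encoding="utf-8")
            (out / "lexicons" / f"{name}.assoc.txt").write_text(
                fig["assoc"] + "\n", encoding="utf-8")
            index.append({"name": name,
                          "image": f"images/{name}.png",
                          "gold": f"gold/{name}.json",
                          "caption": f"lexicons/{name}.caption.txt",
                          "assoc": f"lexicons/{name}.assoc.txt"})
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump({"profile": profile, "seed": seed, "n_figures": n_figures,
                       "coverage": coverage, "figures": index}, fh, indent=2)
    return manifest


def load_gold(path) -> list[dict]:
    """Read a gold annotation file (list of id/x/y/w/h/text records)."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
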