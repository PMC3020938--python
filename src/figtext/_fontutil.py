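"""Shared font discovery for the synthetic renderer and the fixture OCR
engine (both must draw glyphs with the same faces)."""

from __future__ import annotations

from functools import lru_cache

from PIL import ImageFont

FACES = {"sans": "DejaVu Sans", "serif": "DejaVu Serif"}


@lru_cache(maxsize=None)
def find_font_path(face: str = "sans") -> str:
    """Resolve a bundled font file for the given face ('sans' or 'serif')."""
    from matplotlib import font_manager

    family = FACES.get(face, face)
    return font_manager.findfont(family, fallback_to_default=True)


@lru_cache(maxsize=None)
def load_font(face: str = "sans", size: int = 16) -> ImageFont.FreeTypeFont:
    return ImageFont.truetype(find_font_path(face), size=size)
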