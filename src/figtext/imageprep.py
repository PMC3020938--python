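"""Image preprocessing: contrast stretching, gray-polarity decision, bicubic up-sampling.

The pipeline works on 8-bit grayscale rasters (2-D ``numpy.uint8`` arrays).
Figure text is normalized to *dark text on a bright background*: if the mean
gray level ``M`` of the input is at or below a threshold ``delta`` the image
is inverted before localization, so downstream stages only ever see one
polarity.

Contrast stretching is a three-segment piecewise-linear intensity map that
pushes near-black levels (below ``a1``) toward black and near-white levels
(above ``a2``) toward white while keeping the mid-range slope close to one,
so the contrast of non-text content is essentially preserved while text
strokes (which in figures sit at the extremes of the gray scale) gain
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "ContrastParams",
    "PolarityDecision",
    "as_gray_image",
    "load_image",
    "save_image",
    "rgb_to_gray",
    "mean_gray",
    "invert",
    "decide_polarity",
    "stretch_contrast",
    "contrast_lut",
    "upsample_bicubic",
]

#: ITU-R 601 luma weights used for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its documented invariants."""


@dataclass(frozen=True)
class ContrastParams:
    """Breakpoints of the piecewise-linear contrast-stretching transform.

    Gray levels in ``[0, a1]`` map onto ``[0, dark_target]``, ``[a1, a2]``
    onto ``[dark_target, bright_target]`` and ``[a2, 255]`` onto
    ``[bright_target, 255]``.  Defaults put the breakpoints at the observed
    gray levels of black (``< 10``) and white (``> 230``) figure text.
    """

    a1: int = 10
    a2: int = 230
    dark_target: int = 2
    bright_target: int = 253

    def __post_init__(self) -> None:
        if not (0 <= self.dark_target <= self.a1 < self.a2 <= self.bright_target <= 255):
            raise ConfigurationError(
                "contrast params must satisfy 0 <= dark_target <= a1 < a2 "
                f"<= bright_target <= 255, got {self}"
            )


@dataclass(frozen=True)
class PolarityDecision:
    """Outcome of the gray-polarity test: mean gray ``M``, threshold ``delta``
    and whether the image was inverted (``M <= delta``)."""

    mean_gray: float
    threshold: float
    inverted: bool


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Validate and coerce ``arr`` into the pipeline's working representation
    (2-D uint8). Raises ``ValueError`` for empty or mis-shaped input."""
    a = np.asarray(arr)
    if a.ndim == 3:
        a = rgb_to_gray(a)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"expected a non-empty 2-D gray image, got shape {a.shape}")
    if a.dtype != np.uint8:
        a = np.clip(np.rint(a), 0, 255).astype(np.uint8)
    return a


def rgb_to_gray(arr: np.ndarray) -> np.ndarray:
    """Convert an RGB(A) raster to 8-bit gray with ITU-R 601 luma weights."""
    a = np.asarray(arr, dtype=float)
    if a.ndim != 3 or a.shape[2] < 3:
        raise ValueError(f"expected an RGB image, got shape {a.shape}")
    g = a[..., :3] @ _LUMA
    return np.clip(np.rint(g), 0, 255).astype(np.uint8)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF raster as a gray image."""
    with Image.open(path) as im:
        if im.mode in ("L", "I;16", "1"):
            return as_gray_image(np.asarray(im.convert("L")))
        return rgb_to_gray(np.asarray(im.convert("RGB")))


def save_image(img: np.ndarray, path) -> None:
    """Write a gray image as PNG (debugging artifacts)."""
    Image.fromarray(as_gray_image(img), mode="L").save(path)


def mean_gray(img: np.ndarray) -> float:
    """Average gray level ``M`` of an image."""
    return float(as_gray_image(img).mean())


def invert(img: np.ndarray) -> np.ndarray:
    """Photometric inversion ``p -> 255 - p`` (an involution)."""
    return (255 - as_gray_image(img)).astype(np.uint8)


def decide_polarity(img: np.ndarray, threshold: float = 128.0) -> tuple[np.ndarray, PolarityDecision]:
    """Normalize text polarity to dark-on-bright.

    If the mean gray level exceeds ``threshold`` the background is considered
    bright and the image is returned unchanged; otherwise (including an exact
    tie) the image is inverted.
    """
    if not (0 <= threshold <= 255):
        raise ValueError(f"threshold must be in [0, 255], got {threshold}")
    img = as_gray_image(img)
    m = mean_gray(img)
    if m > threshold:
        return img, PolarityDecision(m, threshold, inverted=False)
    return invert(img), PolarityDecision(m, threshold, inverted=True)


def contrast_lut(params: ContrastParams = ContrastParams()) -> np.ndarray:
    """256-entry lookup table of the piecewise-linear stretching transform."""
    nodes_x = [0.0, float(params.a1), float(params.a2), 255.0]
    nodes_y = [0.0, float(params.dark_target), float(params.bright_target), 255.0]
    lut = np.interp(np.arange(256), nodes_x, nodes_y)
    return np.clip(np.rint(lut), 0, 255).astype(np.uint8)


def stretch_contrast(img: np.ndarray, params: ContrastParams = ContrastParams()) -> np.ndarray:
    """Apply the modified contrast-stretching transform.

    Endpoints are fixed (0 -> 0, 255 -> 255) and the map is monotone
    non-decreasing, so gray-level order is preserved.
    """
    return contrast_lut(params)[as_gray_image(img)]


def upsample_bicubic(img: np.ndarray, factor: int = 3) -> np.ndarray:
    """Up-sample by an integer factor with bicubic interpolation.

    Uses cubic-convolution resampling with kernel parameter -0.5
    (Catmull-Rom), which reproduces linear intensity ramps exactly away from
    the borders.  ``factor == 1`` returns the image unchanged.
    """
    img = as_gray_image(img)
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"up-sampling factor must be an integer >= 1, got {factor!r}")
    if factor == 1:
        return img.copy()
    h, w = img.shape
    out = Image.fromarray(img, mode="L").resize((w * factor, h * factor), Image.BICUBIC)
    return np.asarray(out, dtype=np.uint8)
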