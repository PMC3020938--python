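"""Text localization: binarize, extract strong edges, group connected
components into text regions, and score localization against ground truth.

Stages (mirroring the A->D progression of the preprocessing pipeline):

1. ``binarize`` — local adaptive threshold on the contrast-stretched,
   polarity-normalized image; foreground marks dark (text-candidate) pixels.
2. ``extract_edges`` — Sobel gradient magnitude thresholded at the strong-edge
   level, restricted to (a 1-px dilation of) the foreground.
3. ``connected_components`` — 8-connected components with bounding boxes.
4. ``filter_components`` — geometric constraints (area, height, aspect ratio)
   remove non-text blobs.
5. ``merge_regions`` — adjacent character boxes are merged into text regions
   by a horizontal morphological-closing rule with transitive closure.

Evaluation follows region counting: correctly detected (N_c), falsely
detected (N_f) and missed (N_m) regions under greedy one-to-one IoU matching,
with recall N_c/(N_c+N_m), precision N_c/(N_c+N_f) and their harmonic mean.

Boxes are 0-based, half-open ``(x, y, w, h)`` everywhere, including JSON/CSV
output.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure

from .imageprep import ContrastParams, PolarityDecision, as_gray_image, decide_polarity, stretch_contrast

__all__ = [
    "Box",
    "ComponentStats",
    "TextRegion",
    "LocalizationCounts",
    "GeometricConstraints",
    "MergeParams",
    "LocalizerConfig",
    "binarize",
    "extract_edges",
    "connected_components",
    "filter_components",
    "merge_regions",
    "localize_text",
    "match_regions",
    "localization_prf",
    "box_iou",
    "regions_to_json",
    "regions_from_json",
    "regions_to_csv",
]

Box = tuple[int, int, int, int]  # (x, y, w, h), 0-based, half-open


@dataclass(frozen=True)
class ComponentStats:
    """A connected component candidate character: box, pixel area, aspect."""

    bbox: Box
    area: int

    @property
    def aspect_ratio(self) -> float:
        return self.bbox[2] / self.bbox[3]


@dataclass(frozen=True)
class TextRegion:
    """A localized figure-text region (merged character components)."""

    bbox: Box
    component_ids: tuple[int, ...]
    polarity: PolarityDecision | None = None


@dataclass(frozen=True)
class LocalizationCounts:
    n_correct: int  # N_c
    n_false: int    # N_f
    n_missed: int   # N_m


@dataclass(frozen=True)
class GeometricConstraints:
    """Size/aspect constraints a character component must satisfy.

    ``max_area_frac`` and ``max_h_frac`` are resolved against the image shape
    at filtering time; set the absolute fields to override.
    """

    min_area: int = 9
    max_area: int | None = None
    min_h: int = 5
    max_h: int | None = None
    max_aspect: float = 10.0
    max_area_frac: float = 0.20
    max_h_frac: float = 0.50

    def resolve(self, image_shape: tuple[int, int]) -> "GeometricConstraints":
        h, w = image_shape
        out = self
        if out.max_area is None:
            out = replace(out, max_area=int(round(self.max_area_frac * h * w)))
        if out.max_h is None:
            out = replace(out, max_h=int(round(self.max_h_frac * h)))
        return out


@dataclass(frozen=True)
class MergeParams:
    """Horizontal closing rule: merge two boxes when the horizontal gap is at
    most ``gap_factor`` times the taller box's height and the vertical overlap
    is at least ``overlap_factor`` times the shorter box's height."""

    gap_factor: float = 1.0
    overlap_factor: float = 0.5


@dataclass(frozen=True)
class LocalizerConfig:
    contrast: ContrastParams = field(default_factory=ContrastParams)
    polarity_delta: float = 128.0
    binarize_block_size: int = 25
    binarize_offset: float = 10.0
    edge_threshold: float = 60.0 / 255.0
    constraints: GeometricConstraints = field(default_factory=GeometricConstraints)
    merge: MergeParams = field(default_factory=MergeParams)
    rescue_diacritics: bool = True


def binarize(img: np.ndarray, block_size: int = 25, offset: float = 10.0) -> np.ndarray:
    """Local adaptive threshold; True marks dark (text-candidate) pixels.

    A pixel is foreground when it is darker than the local mean (window
    ``block_size``) minus ``offset`` gray levels, so constant images yield an
    empty mask.
    """
    img = as_gray_image(img)
    if block_size % 2 == 0:
        block_size += 1
    thresh = filters.threshold_local(img.astype(float), block_size=block_size,
                                     method="mean", offset=offset)
    return img < thresh


def extract_edges(img: np.ndarray, mask: np.ndarray, threshold: float = 60.0 / 255.0) -> np.ndarray:
    """Strong edges of foreground objects.

    Sobel gradient magnitude (on intensities scaled to [0, 1]) must exceed
    ``threshold``, and edge pixels are restricted to the 1-pixel dilation of
    the foreground mask.
    """
    img = as_gray_image(img)
    if mask.shape != img.shape:
        raise ValueError("mask and image shapes differ")
    grad = filters.sobel(img.astype(float) / 255.0)
    support = ndi.binary_dilation(mask, structure=np.ones((3, 3), bool))
    return (grad > threshold) & support


def connected_components(mask: np.ndarray) -> list[ComponentStats]:
    """Maximal 8-connected components of a binary mask, in label order."""
    labels = measure.label(np.asarray(mask, bool), connectivity=2)
    out: list[ComponentStats] = []
    for p in measure.regionprops(labels):
        r0, c0, r1, c1 = p.bbox
        out.append(ComponentStats(bbox=(c0, r0, c1 - c0, r1 - r0), area=int(p.area)))
    return out


def filter_components(components: list[ComponentStats],
                      constraints: GeometricConstraints,
                      image_shape: tuple[int, int] | None = None) -> list[ComponentStats]:
    """Keep components within the area/height/aspect constraints."""
    c = constraints.resolve(image_shape) if image_shape is not None else constraints
    max_area = c.max_area if c.max_area is not None else np.inf
    max_h = c.max_h if c.max_h is not None else np.inf
    kept = []
    for comp in components:
        _, _, w, h = comp.bbox
        if not (c.min_area <= comp.area <= max_area):
            continue
        if not (c.min_h <= h <= max_h):
            continue
        if not (1.0 / c.max_aspect <= comp.aspect_ratio <= c.max_aspect):
            continue
        kept.append(comp)
    return kept


def _union_box(a: Box, b: Box) -> Box:
    x0 = min(a[0], b[0]); y0 = min(a[1], b[1])
    x1 = max(a[0] + a[2], b[0] + b[2]); y1 = max(a[1] + a[3], b[1] + b[3])
    return (x0, y0, x1 - x0, y1 - y0)


def _mergeable(a: Box, b: Box, params: MergeParams) -> bool:
    # horizontal gap between boxes (0 if they overlap horizontally)
    gap = max(a[0], b[0]) - min(a[0] + a[2], b[0] + b[2])
    if gap > params.gap_factor * max(a[3], b[3]):
        return False
    overlap = min(a[1] + a[3], b[1] + b[3]) - max(a[1], b[1])
    return overlap >= params.overlap_factor * min(a[3], b[3])


def merge_regions(components: list[ComponentStats],
                  params: MergeParams = MergeParams()) -> list[TextRegion]:
    """Merge adjacent character components into text regions.

    Union-find closure over the pairwise merge rule; overlapping result boxes
    are merged again so the returned regions are mutually non-overlapping.
    Regions are returned in reading order (top-to-bottom, then left-to-right).
    """
    n = len(components)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            if _mergeable(components[i].bbox, components[j].bbox, params):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    regions = [
        TextRegion(
            bbox=_box_union_of([components[i].bbox for i in ids]),
            component_ids=tuple(sorted(ids)),
        )
        for ids in groups.values()
    ]

    # collapse any overlapping region boxes (closure can still leave overlaps)
    changed = True
    while changed:
        changed = False
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                if _boxes_overlap(regions[i].bbox, regions[j].bbox):
                    merged = TextRegion(
                        bbox=_union_box(regions[i].bbox, regions[j].bbox),
                        component_ids=tuple(sorted(regions[i].component_ids
                                                   + regions[j].component_ids)),
                    )
                    regions[i] = merged
                    del regions[j]
                    changed = True
                    break
            if changed:
                break

    regions.sort(key=lambda r: (r.bbox[1], r.bbox[0]))
    return regions


def _box_union_of(boxes: list[Box]) -> Box:
    out = boxes[0]
    for b in boxes[1:]:
        out = _union_box(out, b)
    return out


def _boxes_overlap(a: Box, b: Box) -> bool:
    return (a[0] < b[0] + b[2] and b[0] < a[0] + a[2]
            and a[1] < b[1] + b[3] and b[1] < a[1] + a[3])


def _rescue_diacritics(regions: list[TextRegion],
                       rejected: list[ComponentStats]) -> list[TextRegion]:
    """Re-attach small rejected components (i/j dots, accents) sitting directly
    above or below a region whose x-range contains them."""
    out = list(regions)
    for comp in rejected:
        cx0, cy0, cw, ch = comp.bbox
        ccx = cx0 + cw / 2.0
        for k, reg in enumerate(out):
            x, y, w, h = reg.bbox
            if not (x <= ccx <= x + w):
                continue
            vgap = max(y - (cy0 + ch), cy0 - (y + h))
            if vgap <= 0.5 * h and ch <= 0.5 * h:
                out[k] = TextRegion(bbox=_union_box(reg.bbox, comp.bbox),
                                    component_ids=reg.component_ids)
                break
    return out


def localize_text(img: np.ndarray, config: LocalizerConfig = LocalizerConfig()) -> list[TextRegion]:
    """Full localization chain on a raw figure image.

    stretch_contrast -> decide_polarity -> binarize -> extract_edges ->
    connected_components -> filter_components -> merge_regions; regions come
    back in reading order, each carrying the polarity decision.
    """
    img = as_gray_image(img)
    stretched = stretch_contrast(img, config.contrast)
    norm, decision = decide_polarity(stretched, config.polarity_delta)
    mask = binarize(norm, config.binarize_block_size, config.binarize_offset)
    edges = extract_edges(norm, mask, config.edge_threshold)
    # components over the union of foreground and its strong edges: edges
    # recover thin strokes the local threshold may split
    comps = connected_components(mask | edges)
    kept = filter_components(comps, config.constraints, img.shape)
    regions = merge_regions(kept, config.merge)
    if config.rescue_diacritics:
        kept_set = set(kept)
        rejected = [c for c in comps if c not in kept_set]
        regions = _rescue_diacritics(regions, rejected)
    return [replace(r, polarity=decision) for r in regions]


def box_iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ix = max(0, min(a[0] + a[2], b[0] + b[2]) - max(a[0], b[0]))
    iy = max(0, min(a[1] + a[3], b[1] + b[3]) - max(a[1], b[1]))
    inter = ix * iy
    if inter == 0:
        return 0.0
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union


def match_regions(predicted: list[TextRegion] | list[Box],
                  gold: list[Box],
                  iou_threshold: float = 0.5) -> LocalizationCounts:
    """Greedy one-to-one matching of predicted to gold boxes by descending
    IoU; a pair matches when IoU >= ``iou_threshold``."""
    pred_boxes = [r.bbox if isinstance(r, TextRegion) else tuple(r) for r in predicted]
    pairs = sorted(
        ((box_iou(p, g), pi, gi)
         for pi, p in enumerate(pred_boxes)
         for gi, g in enumerate(gold)),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    used_p: set[int] = set()
    used_g: set[int] = set()
    n_correct = 0
    for iou, pi, gi in pairs:
        if iou < iou_threshold:
            break
        if pi in used_p or gi in used_g:
            continue
        used_p.add(pi)
        used_g.add(gi)
        n_correct += 1
    return LocalizationCounts(
        n_correct=n_correct,
        n_false=len(pred_boxes) - n_correct,
        n_missed=len(gold) - n_correct,
    )


def localization_prf(counts: LocalizationCounts) -> tuple[float, float, float]:
    """Precision N_c/(N_c+N_f), recall N_c/(N_c+N_m) and their harmonic mean;
    empty denominators yield 0 by convention."""
    nc, nf, nm = counts.n_correct, counts.n_false, counts.n_missed
    p = nc / (nc + nf) if nc + nf else 0.0
    r = nc / (nc + nm) if nc + nm else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def regions_to_json(regions: list[TextRegion], path=None) -> str:
    """Serialize regions as a JSON list of ``{id, x, y, w, h}``."""
    payload = [
        {"id": i, "x": r.bbox[0], "y": r.bbox[1], "w": r.bbox[2], "h": r.bbox[3]}
        for i, r in enumerate(regions)
    ]
    text = json.dumps(payload, indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
    return text


def regions_from_json(path) -> list[dict]:
    """Load region (or ground-truth) records; each has x/y/w/h and optionally
    an annotated ``text`` field."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def regions_to_csv(regions: list[TextRegion], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "x", "y", "w", "h"])
        for i, r in enumerate(regions):
            writer.writerow([i, *r.bbox])
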