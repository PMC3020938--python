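"""Binarization, edges, components, geometric filtering, merging, matching."""

import numpy as np
import pytest
from skimage import filters as skfilters

from figtext.imageprep import invert
from figtext.localizer import (ComponentStats, GeometricConstraints,
                               LocalizationCounts, MergeParams, TextRegion,
                               binarize, box_iou, connected_components,
                               extract_edges, filter_components,
                               localization_prf, localize_text, match_regions,
                               merge_regions, regions_from_json,
                               regions_to_json)

from oracles import flood_fill_components


# -- binarize ----------------------------------------------------------------

def test_binarize_bimodal_image_matches_otsu_oracle():
    # stroke-width dark marks on a flat background: any reasonable local or
    # global threshold separates the two levels identically
    img = np.full((60, 60), 220, np.uint8)
    img[20:23, 15:40] = 20
    img[40:43, 5:30] = 20
    mask = binarize(img)
    otsu = img <= skfilters.threshold_otsu(img)
    assert np.array_equal(mask, otsu)


def test_binarize_constant_image_is_empty():
    assert not binarize(np.full((40, 40), 128, np.uint8)).any()


# -- edges -------------------------------------------------------------------

def test_edges_constant_image_empty():
    img = np.full((30, 30), 100, np.uint8)
    assert not extract_edges(img, np.zeros_like(img, bool)).any()


def test_edges_square_boundary_ring():
    img = np.full((30, 30), 255, np.uint8)
    img[10:20, 10:20] = 0
    mask = img < 128
    edges = extract_edges(img, mask)
    assert edges.any()
    # every edge pixel sits within 1 px (Chebyshev) of the square's boundary
    ys, xs = np.nonzero(edges)
    for y, x in zip(ys, xs):
        on_boundary_band = (8 <= y <= 21 and 8 <= x <= 21) and not (12 <= y <= 17 and 12 <= x <= 17)
        assert on_boundary_band
    # and the ring surrounds the square on all four sides
    assert ys.min() <= 10 and ys.max() >= 19 and xs.min() <= 10 and xs.max() >= 19


def test_soft_gradient_below_threshold_yields_no_edges():
    # ramp of 1 gray level per pixel: gradient ~1/255 << 60/255
    img = np.tile(np.arange(100, 160, dtype=np.uint8), (30, 1))
    mask = np.ones_like(img, bool)
    assert not extract_edges(img, mask).any()


# -- connected components ----------------------------------------------------

def test_components_empty_mask():
    assert connected_components(np.zeros((10, 10), bool)) == []


def test_components_match_flood_fill_oracle(rng):
    for _ in range(20):
        mask = rng.random((15, 20)) < 0.3
        got = sorted(c.bbox for c in connected_components(mask))
        assert got == flood_fill_components(mask.tolist())


def test_two_blocks_and_diagonal_touch():
    mask = np.zeros((10, 12), bool)
    mask[2:5, 1:4] = True
    mask[2:5, 7:10] = True
    comps = connected_components(mask)
    assert sorted(c.bbox for c in comps) == [(1, 2, 3, 3), (7, 2, 3, 3)]
    diag = np.zeros((4, 4), bool)
    diag[1, 1] = diag[2, 2] = True
    assert len(connected_components(diag)) == 1  # 8-connectivity


# -- geometric filtering -----------------------------------------------------

def comp(x, y, w, h):
    return ComponentStats(bbox=(x, y, w, h), area=w * h)


def test_filter_unlimited_is_identity():
    comps = [comp(0, 0, 3, 5), comp(10, 10, 4, 8)]
    vacuous = GeometricConstraints(min_area=1, max_area=10 ** 9, min_h=1,
                                   max_h=10 ** 9, max_aspect=10 ** 9)
    assert filter_components(comps, vacuous) == comps


def test_filter_rejects_strip_and_speck():
    strip = comp(0, 0, 40, 1)     # aspect 40 > 10
    speck = comp(0, 0, 2, 2)      # area 4 < 9
    ok = comp(0, 0, 6, 9)
    kept = filter_components([strip, speck, ok],
                             GeometricConstraints(), image_shape=(100, 100))
    assert kept == [ok]


# -- merging -----------------------------------------------------------------

def test_merge_single_component():
    regions = merge_regions([comp(5, 5, 8, 10)])
    assert len(regions) == 1 and regions[0].bbox == (5, 5, 8, 10)


def test_merge_adjacent_characters():
    a, b = comp(0, 0, 8, 10), comp(11, 0, 8, 10)  # 3 px apart, same line
    regions = merge_regions([a, b], MergeParams(gap_factor=1.0, overlap_factor=0.5))
    assert len(regions) == 1
    assert regions[0].bbox == (0, 0, 19, 10)


def test_vertically_disjoint_boxes_stay_separate():
    a, b = comp(0, 0, 8, 10), comp(11, 20, 8, 10)
    regions = merge_regions([a, b], MergeParams())
    assert len(regions) == 2


def test_merge_closure_is_transitive():
    chain = [comp(i * 11, 0, 8, 10) for i in range(5)]  # each 3 px from next
    regions = merge_regions(chain)
    assert len(regions) == 1
    assert regions[0].component_ids == (0, 1, 2, 3, 4)


# -- matching and scoring ----------------------------------------------------

def region(x, y, w, h):
    return TextRegion(bbox=(x, y, w, h), component_ids=(0,))


def test_match_perfect_prediction():
    gold = [(0, 0, 10, 10), (20, 0, 10, 10)]
    pred = [region(*g) for g in gold]
    c = match_regions(pred, gold)
    assert (c.n_correct, c.n_false, c.n_missed) == (2, 0, 0)


def test_match_counts_extras_and_misses():
    gold = [(0, 0, 10, 10), (20, 0, 10, 10), (40, 0, 10, 10), (60, 0, 10, 10)]
    pred = [region(0, 0, 10, 10), region(20, 0, 10, 10), region(40, 0, 10, 10),
            region(100, 100, 10, 10)]
    c = match_regions(pred, gold)
    assert (c.n_correct, c.n_false, c.n_missed) == (3, 1, 1)


def test_one_to_one_matching_over_duplicates():
    gold = [(0, 0, 10, 10)]
    pred = [region(0, 0, 10, 10), region(1, 0, 10, 10)]
    c = match_regions(pred, gold)
    assert (c.n_correct, c.n_false, c.n_missed) == (1, 1, 0)


def test_gold_count_conservation(rng):
    gold = [(int(x), int(y), 10, 10)
            for x, y in rng.integers(0, 200, (6, 2))]
    pred = [region(int(x), int(y), 10, 10)
            for x, y in rng.integers(0, 200, (9, 2))]
    c = match_regions(pred, gold)
    assert c.n_correct + c.n_missed == len(gold)


def test_localization_prf_arithmetic():
    p, r, f1 = localization_prf(LocalizationCounts(3, 1, 1))
    assert (p, r, f1) == (0.75, 0.75, 0.75)
    assert localization_prf(LocalizationCounts(5, 0, 0)) == (1.0, 1.0, 1.0)
    assert localization_prf(LocalizationCounts(0, 0, 0)) == (0.0, 0.0, 0.0)


def test_iou_basics():
    assert box_iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0
    assert box_iou((0, 0, 10, 10), (20, 20, 5, 5)) == 0.0


# -- end-to-end localization -------------------------------------------------

def test_blank_image_has_no_regions():
    assert localize_text(np.full((100, 100), 240, np.uint8)) == []


def test_easy_figures_are_localized(easy_dataset):
    for fig in easy_dataset["figures"][:4]:
        gold = [(g["x"], g["y"], g["w"], g["h"]) for g in fig["gold"]]
        regions = localize_text(fig["image"])
        counts = match_regions(regions, gold)
        assert counts.n_missed == 0
        assert counts.n_false == 0
        # each matched region covers >= 90% of its gold box area
        for g in gold:
            best = max(regions, key=lambda r: box_iou(r.bbox, g))
            bx, by, bw, bh = best.bbox
            ix = max(0, min(bx + bw, g[0] + g[2]) - max(bx, g[0]))
            iy = max(0, min(by + bh, g[1] + g[3]) - max(by, g[1]))
            assert ix * iy >= 0.9 * g[2] * g[3]


def test_localization_invariant_under_inversion(easy_dataset):
    fig = easy_dataset["figures"][0]
    direct = [r.bbox for r in localize_text(fig["image"])]
    flipped = [r.bbox for r in localize_text(invert(fig["image"]))]
    assert direct == flipped


def test_regions_within_bounds_and_reading_order(easy_dataset):
    fig = easy_dataset["figures"][1]
    h, w = fig["image"].shape
    regions = localize_text(fig["image"])
    for r in regions:
        x, y, bw, bh = r.bbox
        assert 0 <= x and 0 <= y and x + bw <= w and y + bh <= h
    tops = [r.bbox[1] for r in regions]
    assert tops == sorted(tops)


def test_region_json_round_trip(tmp_path):
    regions = [region(1, 2, 3, 4), region(10, 20, 30, 40)]
    path = tmp_path / "regions.json"
    regions_to_json(regions, path)
    loaded = regions_from_json(path)
    assert [(d["x"], d["y"], d["w"], d["h"]) for d in loaded] \
        == [r.bbox for r in regions]
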