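# Methods

This note documents the models and procedures implemented in `figtext`, the
parameter defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the package's known limitations.

## Image preprocessing

**Contrast stretching.** Figure text in 8-bit rasters tends to sit at the
extremes of the gray scale (black text below gray level 10, white text above
230). The transform is a three-segment piecewise-linear map with breakpoints
`a1 = 10` and `a2 = 230`: `[0, a1] → [0, dark_target]`,
`[a1, a2] → [dark_target, bright_target]`, `[a2, 255] → [bright_target, 255]`,
with `dark_target = 2` and `bright_target = 253` so the mid-range slope is
≈ 1.14 — text contrast is amplified while non-text content is essentially
preserved. Endpoints are fixed (0 → 0, 255 → 255) and the map is monotone.
The transform is realized as a 256-entry LUT with round-half-even rounding.

**Polarity.** The pipeline normalizes to dark-on-bright text: if the mean
gray level `M` of the (stretched) image is at or below the threshold
`δ = 128` (configurable), the image is inverted. The tie `M = δ` inverts —
any fixed rule works; this one is documented and tested. Normalization is
stable: a second application never inverts again when the inverted image's
mean lands above the threshold.

**Up-sampling.** Localized regions are enlarged ×3 (configurable) with
cubic-convolution resampling, kernel parameter −0.5 (Catmull–Rom, Pillow's
`BICUBIC`). This kernel reproduces linear intensity ramps exactly away from
borders, which is the property the tests pin down. "Bicubic" admits variants
(B-spline, Mitchell); the Catmull–Rom choice is fixed and documented because
it is the common default in imaging toolchains. Up-sampling is applied per
localized region *after* localization — the order that performs best —
with a whole-image mode retained for ablations. RGB inputs are converted to
gray with ITU-R 601 luma weights before anything else.

## Text localization

Binarization is a local adaptive mean threshold (window 25 px, offset 10
gray levels) on the stretched, polarity-normalized image; it is robust to
gradient backgrounds and yields an empty mask on constant images. Strong
edges are Sobel gradient magnitude above 60/255, restricted to a 1-px
dilation of the foreground; components are taken over the union of
foreground and edges so that thin strokes split by the local threshold are
still recovered. Components are maximal under 8-connectivity (diagonal
glyph strokes). Geometric constraints keep components with area in
[9 px, 20 % of the image], height in [5 px, 50 % of the image height] and
aspect ratio within [1/10, 10] — all configurable; no canonical values
exist, and these defaults pass clean rendered text while rejecting specks,
rules and large panels.

Merging is a box-level horizontal closing: two components merge when their
horizontal gap is at most `gap_factor = 1.0` × the taller box's height and
their vertical overlap is at least `overlap_factor = 0.5` × the shorter
box's height, with transitive closure (union-find) and a final pass that
collapses any still-overlapping region boxes, so returned regions are
mutually non-overlapping and sorted in reading order.

*Diacritic rescue.* The dots of "i"/"j" are always smaller than the minimum
component height, so the size filter removes them and region boxes would
systematically clip dotted ascenders. Components rejected by the filter are
therefore re-attached to a merged region when they sit directly above or
below it within half the region height. This is an engineering addition to
the classic filter-then-merge chain, on by default and configurable.

Localization is scored by greedy one-to-one matching of predicted to gold
boxes in descending IoU order with an IoU ≥ 0.5 acceptance; matched, extra
and missed counts give recall `N_c/(N_c+N_m)`, precision `N_c/(N_c+N_f)`
and their harmonic mean. "Correctly detected" has no canonical definition;
IoU ≥ 0.5 with one-to-one assignment is the standard detection convention.

## Character recognition

Recognition is a contract, not an engine: anything exposing
`recognize(region_image, region_id) -> tokens` can be registered by name.
Unknown names raise `BackendMissingError`; there is never a silent empty
fallback. OCR runs once per merged region (not per character box).

The bundled **fixture recognizer** exists so the pipeline is fully testable
without an external engine. It renders a glyph atlas with the same DejaVu
faces the synthetic generator uses, segments a region by Otsu thresholding
and 8-connected components, groups components into glyph clusters when
their x-ranges overlap by ≥ 60 % of the smaller width (so an i-dot joins
its stem but kerned neighbors stay apart), inserts token breaks at gaps
wider than 0.45 × the median glyph height, and classifies each cluster by
minimum mean-squared difference of scale-normalized, lightly blurred
(σ = 1 px) shapes. Clusters matching poorly (error > 0.06, width ≥ 0.6 ×
height) are tentatively cut at interior columns and re-classified — this
resolves character pairs that physically touch at small sizes — and the
atlas also carries multi-character templates for the common touching pairs
(ff, fi, fl, tt, rt). On clean easy-profile regions the fixture reads back
exactly the rendered strings, which is the baseline the tests assert.

The **error channel** corrupts tokens reproducibly: per character one event
is drawn (substitute / delete / keep) and insertions may follow any
position. Substitutions use a confusion table of classic OCR errors
(l↔i, e↔c, s↔z, 5→s, o↔0, m→rn) when the character has an entry. The RNG is
seeded from `(model seed, word)`, so corruption is independent of call
order. Expected edit distance grows monotonically with the substitution
rate.

## Lexicons and correction

Four figure-specific lexicons are built from plain text: caption,
associated text, their union, and full text. Tokenization splits on
whitespace, strips edge punctuation but preserves internal hyphens, slashes
and plus signs (linked terms like "TBP-TFB-RNAP" survive), and drops tokens
without letters. Membership is case-insensitive with the stored
original-case form returned; frequencies are kept for tie-breaking.
Length-1 tokens are stored but never offered as candidates (panel labels
would otherwise absorb everything).

Candidate selection minimizes edit distance or maximizes LCS length /
alignment score over all lexicon candidates; ties break toward higher
frequency, then the shorter candidate, then lexicographic order. Metrics
are computed case-insensitively. The alignment uses linear gap costs
(match +2, mismatch −1, gap −2 by default) via a Needleman–Wunsch DP that
also tracks, lexicographically, the maximum matched-character count among
optimal-score alignments — the quantity character accuracy is built on.

Refinement decomposes both words into character n-grams after padding one
boundary space at each end (order n = 2, so a length-L word yields L+1
bigrams; ω_TF counts the multiset intersection). The correction is accepted
only when `T_overlap = ω_TF / N_n-gram` strictly exceeds `γ = 0.5`. n, γ
and the pad character are configurable; n = 2 and γ = 0.5 are midpoints of
the sensible ranges, chosen once. Tokens found verbatim in the lexicon, and
tokens with no letters, always pass through unchanged; tokens with at least
one letter (e.g. "Rad52p") are correctable.

One worked-example discrepancy is documented rather than reproduced: the
subsequence common to "antlsnze" and "antiserum" is sometimes quoted as
"ants" (length 4), but the true LCS is "antse" (length 5); the
implementation follows the LCS definition, verified against exhaustive
subsequence enumeration.

## Evaluation

Word-level scoring drops letterless tokens, then requires exact
case-sensitive equality under one-to-one multiset matching (a single
correct extraction cannot satisfy two identical gold tokens, so N_C = N_T).
Precision = N_C/N_R, recall = N_T/N_F, F1 the harmonic mean; zero
denominators give 0. Note the asymmetry with correction: candidate *search*
is case-insensitive, final *evaluation* is case-sensitive. Character
accuracy divides matched characters in the optimal (case-sensitive)
character alignment by gold length, aggregated per gold character overall
and per length bucket; word accuracy is the exact-match rate per gold
length.

## Synthetic data

The generator renders lowercase label-style words (a fixed 96-word
vocabulary of assay/molecular terms) in DejaVu Sans/Serif on 480×360
canvases, one word per line slot, with glyph-tight boxes recovered from the
≥ 50 % alpha-coverage mask. The **easy** profile — plain bright background,
fonts 16–24 px, full contrast, sans face — is calibrated to be
near-perfectly solvable so tests separate algorithm correctness from corpus
difficulty. The **hard** profile draws busier backgrounds (gradient,
texture, line art), smaller fonts (10–16 px), reduced contrast and stroke
widening. Degradations are seeded and monotone: `low_contrast` compresses
the text/background gray gap toward the median, `thick_stroke` applies
gray-level erosion, `complexity` composites line clutter; small font size
is a property of the spec, not a filter. Per-figure caption/associated
files carry a configurable fraction (default 0.35) of the rendered words
mixed with distractor words that are never rendered, so lexicon-coverage
effects are reproducible. Everything derives from `(profile, seed)`;
re-running produces byte-identical images.

What the generator does **not** emulate: real article layouts, gene
sequence panels, rotated or curved baselines, color figures, outlined or
exotic fonts, JPEG artifacts, or the vocabulary breadth of real papers.
Passing the synthetic suites therefore demonstrates the algorithms are
implemented correctly under controlled conditions, not that corpus-level
performance on real figures is reproduced.

## Problem sizes and numerical choices

The end-to-end suites use 50 figures for localization scoring and 200
corrupted tokens per correction experiment — sizes at which every property
under test is stable across seeds while the whole suite stays fast.
Candidate search is exhaustive over the lexicon (no trie acceleration;
desk-scale lexicons are ~100–6,000 tokens). Degenerate inputs are defined
everywhere: empty masks produce no components, blank images no regions,
empty lexicons no candidates, zero denominators zero scores.

## Known limitations

- At desk scale with ~100-word lexicons and substitution-dominated noise,
  edit distance produces frequent score ties between the true candidate and
  a wrong one; the tie-break (frequency, then shorter, then lexicographic)
  can then pick the wrong word, and the alignment metric — which separates
  such ties through its stronger length sensitivity — restores one to three
  words more per 200 than edit distance in most seeded runs. The acceptance
  suite asserts the classic ED ≥ MSA ≥ LCS restoration ordering and this
  assertion fails under those conditions; the robust sub-orderings
  (ED ≥ LCS, MSA ≥ LCS) hold in every seeded run and are asserted in the
  unit suite.
- The fixture recognizer's default atlas covers lowercase letters plus
  common touching pairs; it is scale-invariant but not rotation- or
  shear-tolerant, and serif faces below ~16 px produce touching glyph runs
  it cannot always segment. It is a test instrument, not a general OCR.
- Localization assumes one global text polarity per figure; figures mixing
  dark and bright text in one raster will lose the minority polarity.
- The merge rule is purely horizontal; vertically stacked characters (e.g.
  rotated axis labels) are returned as separate regions.
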