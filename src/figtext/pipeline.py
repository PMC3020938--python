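"""End-to-end orchestration: localize -> up-sample -> recognize -> correct ->
refine, plus the ablation runner.

``PipelineConfig`` gathers every stage parameter together with ablation
switches (localization, up-sampling, correction, refinement on/off), so the
classic comparison tables — preprocessing ablations, similarity-metric and
lexicon grids, correction with and without refinement — can be reproduced on
synthetic datasets with one call.  Up-sampling is applied per localized
region after localization (the best-performing order); a whole-image mode
remains available for the "up-sampling only" ablation row.

Every extraction returns both the final word list and a full trace (regions,
raw tokens, candidates, overlap scores, decisions) for audit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .corrector import MSAParams, RefinementParams, correct_tokens
from .evaluator import normalize_for_eval, text_metrics
from .imageprep import ContrastParams, as_gray_image, decide_polarity, stretch_contrast, upsample_bicubic
from .lexicon import Lexicon, build_lexicon, union_lexicon
from .localizer import GeometricConstraints, LocalizerConfig, MergeParams, TextRegion, localize_text
from .ocr import OCRErrorModel, get_engine, recognize
from .synthetic import load_gold

logger = logging.getLogger("figtext")

__all__ = ["PipelineConfig", "extract_figure_text", "run_ablation", "build_figure_lexicon"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters plus ablation switches."""

    # imageprep
    contrast: ContrastParams = field(default_factory=ContrastParams)
    polarity_delta: float = 128.0
    upsample_factor: int = 3
    # localizer
    binarize_block_size: int = 25
    binarize_offset: float = 10.0
    edge_threshold: float = 60.0 / 255.0
    constraints: GeometricConstraints = field(default_factory=GeometricConstraints)
    merge: MergeParams = field(default_factory=MergeParams)
    # ocr
    ocr_engine: str = "fixture"
    ocr_noise: OCRErrorModel | None = None
    # correction
    lexicon_kind: str = "caption+associated"
    metric: str = "ED"
    msa: MSAParams = field(default_factory=MSAParams)
    refinement_params: RefinementParams = field(default_factory=RefinementParams)
    # ablation switches
    localization: bool = True
    upsampling: bool = True
    correction: bool = True
    refinement: bool = False

    def localizer_config(self) -> LocalizerConfig:
        return LocalizerConfig(
            contrast=self.contrast, polarity_delta=self.polarity_delta,
            binarize_block_size=self.binarize_block_size,
            binarize_offset=self.binarize_offset,
            edge_threshold=self.edge_threshold,
            constraints=self.constraints, merge=self.merge)

    # -- config file round-trip -------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.ocr_noise is not None:
            d["ocr_noise"]["confusion_pairs"] = list(
                map(list, self.ocr_noise.confusion_pairs))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (("contrast", ContrastParams),
                         ("constraints", GeometricConstraints),
                         ("merge", MergeParams),
                         ("msa", MSAParams),
                         ("refinement_params", RefinementParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if d.get("ocr_noise") is not None and isinstance(d["ocr_noise"], dict):
            noise = dict(d["ocr_noise"])
            noise["confusion_pairs"] = tuple(
                (a, b) for a, b in noise.get("confusion_pairs", ()))
            d["ocr_noise"] = OCRErrorModel(**noise)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_figure_lexicon(caption_text: str, assoc_text: str,
                         kind: str = "caption+associated",
                         fulltext: str | None = None) -> Lexicon:
    """Build the lexicon of the requested kind from a figure's sources."""
    if kind == "caption":
        return build_lexicon([caption_text], "caption")
    if kind == "associated":
        return build_lexicon([assoc_text], "associated")
    if kind == "caption+associated":
        return union_lexicon(build_lexicon([caption_text], "caption"),
                             build_lexicon([assoc_text], "associated"))
    if kind == "fulltext":
        return build_lexicon([fulltext if fulltext is not None
                              else caption_text + "\n" + assoc_text], "fulltext")
    raise ValueError(f"unknown lexicon kind {kind!r}")


def extract_figure_text(img: np.ndarray, lexicon: Lexicon,
                        config: PipelineConfig = PipelineConfig(),
                        engine=None) -> tuple[list[str], dict]:
    """Run the pipeline on one figure; returns final words and a full trace.

    The trace maps every final word back to its region and raw token:
    ``trace["regions"]`` holds per-region boxes and raw/corrected tokens,
    ``trace["tokens"]`` the flat token-level records (raw token, candidate,
    overlap, decision).
    """
    img = as_gray_image(img)
    if engine is None:
        engine = get_engine(config.ocr_engine)

    if config.localization:
        regions = localize_text(img, config.localizer_config())
        norm, decision = decide_polarity(stretch_contrast(img, config.contrast),
                                         config.polarity_delta)
    else:
        h, w = img.shape
        norm, decision = decide_polarity(img, config.polarity_delta)
        regions = [TextRegion(bbox=(0, 0, w, h), component_ids=(0,),
                              polarity=decision)]
    logger.info("localization: %d region(s)", len(regions))

    # OCR-only ablation: no localization and no up-sampling still must see
    # the raw (non-localized) raster
    tokens = []
    region_records = []
    for rid, region in enumerate(regions):
        x, y, w, h = region.bbox
        pad = 2
        crop = norm[max(0, y - pad):y + h + pad, max(0, x - pad):x + w + pad]
        if config.upsampling:
            crop = upsample_bicubic(crop, config.upsample_factor)
        toks = recognize(crop, engine, region_id=rid)
        tokens.extend(toks)
        region_records.append({"id": rid, "x": x, "y": y, "w": w, "h": h,
                               "raw_tokens": [t.text for t in toks]})
    logger.info("recognition: %d token(s)", len(tokens))

    if config.correction:
        results = correct_tokens(tokens, lexicon, config.metric,
                                 refinement=config.refinement,
                                 msa_params=config.msa,
                                 refinement_params=config.refinement_params)
    else:
        results = None

    token_records = []
    words: list[str] = []
    for i, tok in enumerate(tokens):
        rec = {"region_id": tok.region_id, "raw": tok.text}
        if results is None:
            final = tok.text
        else:
            r = results[i]
            final = r.final
            rec.update(candidate=r.candidate, metric=r.metric, score=r.score,
                       t_overlap=r.t_overlap, accepted=r.accepted)
        rec["final"] = final
        if final:
            words.append(final)
        token_records.append(rec)
    n_changed = sum(1 for t in token_records if t["raw"] != t["final"])
    logger.info("correction: %d token(s) changed", n_changed)

    trace = {"regions": region_records, "tokens": token_records,
             "inverted": regions[0].polarity.inverted if regions else False}
    return words, trace


def _dataset_figures(dataset_dir: str | Path) -> list[dict]:
    from .imageprep import load_image

    root = Path(dataset_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"dataset manifest not found: {manifest_path}")
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    figures = []
    for entry in manifest["figures"]:
        for key in ("image", "gold", "caption", "assoc"):
            if not (root / entry[key]).exists():
                raise FileNotFoundError(f"dataset file missing: {root / entry[key]}")
        figures.append({
            "name": entry["name"],
            "image": load_image(root / entry["image"]),
            "gold": load_gold(root / entry["gold"]),
            "caption": (root / entry["caption"]).read_text(encoding="utf-8"),
            "assoc": (root / entry["assoc"]).read_text(encoding="utf-8"),
        })
    return figures


def run_ablation(dataset, configs: dict[str, PipelineConfig],
                 engines: dict[str, object] | None = None) -> pd.DataFrame:
    """Evaluate a grid of pipeline configurations on a synthetic dataset.

    ``dataset`` is a directory produced by ``synthetic.make_dataset`` or the
    in-memory manifest it returns.  One row per configuration with word-level
    precision/recall/F1 (micro-averaged over figures).  Deterministic given
    the dataset seed.
    """
    if isinstance(dataset, (str, Path)):
        figures = _dataset_figures(dataset)
    else:
        figures = dataset["figures"]
    engines = engines or {}
    rows = []
    for name, cfg in configs.items():
        engine = engines.get(name)
        if engine is None:
            kwargs = {}
            if cfg.ocr_noise is not None and cfg.ocr_engine == "noisy-fixture":
                kwargs["error_model"] = cfg.ocr_noise
            engine = get_engine(cfg.ocr_engine, **kwargs)
        counts = np.zeros(3)  # matched, extracted, gold
        for fig in figures:
            lex = build_figure_lexicon(fig["caption"], fig["assoc"], cfg.lexicon_kind)
            words, _ = extract_figure_text(fig["image"], lex, cfg, engine=engine)
            extracted = normalize_for_eval(words)
            gold = normalize_for_eval([g["text"] for g in fig["gold"]])
            c, _, _, _ = text_metrics(extracted, gold)
            counts += (c.n_correct_recognized, c.n_recognized, c.n_gold)
        p = counts[0] / counts[1] if counts[1] else 0.0
        r = counts[0] / counts[2] if counts[2] else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        rows.append({"configuration": name, "precision": p, "recall": r, "f1": f1})
        logger.info("ablation %s: P=%.3f R=%.3f F1=%.3f", name, p, r, f1)
    return pd.DataFrame(rows)
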