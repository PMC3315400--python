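"""End-to-end glue: images -> blocks -> descriptors -> SVM -> image calls.

The descriptor kinds share one contract: a fitted extractor turns a list
of blocks into a feature matrix.  ``lbpc`` needs VAR quantizers trained on
the training images; ``gabor`` needs the filter bank; ``haralick`` is
stateless.  Everything a trained model needs to be reapplied (descriptor
state plus preprocessing configuration) travels inside the model file.
"""

from __future__ import annotations

import numpy as np

from . import classify, gabor, haralick, lbp, preprocess
from .classify import DEFAULT_C, BackgroundImageError, ImageResult, TrainedModel
from .evaluate import ScoreMap, score_map

DESCRIPTOR_KINDS = ("lbpc", "haralick", "gabor")

DEFAULT_PREPROCESS = {
    "scale_factor": preprocess.DEFAULT_SCALE,
    "background_threshold": preprocess.DEFAULT_BACKGROUND_THRESHOLD,
    "morph_radius": preprocess.DEFAULT_MORPH_RADIUS,
    "block_size": preprocess.DEFAULT_BLOCK_SIZE,
    "stride": preprocess.DEFAULT_STRIDE,
    "min_tissue_fraction": preprocess.DEFAULT_MIN_TISSUE,
}


class FeatureExtractor:
    """Fitted descriptor state for one kind, applied block-wise."""

    def __init__(self, kind: str, quantizers=None, bank_config=None):
        if kind not in DESCRIPTOR_KINDS:
            raise ValueError(f"unknown descriptor kind {kind!r}")
        self.kind = kind
        self.quantizers = quantizers
        self.bank_config = bank_config or gabor.GaborBankConfig()
        self._bank = gabor.build_bank(self.bank_config) if kind == "gabor" else None

    @classmethod
    def fit(cls, kind: str, train_grays, train_masks=None,
            bank_config=None) -> "FeatureExtractor":
        """Train descriptor state (VAR quantizers) on the training images."""
        quantizers = None
        if kind == "lbpc":
            quantizers = lbp.train_default_quantizers(train_grays, masks=train_masks)
        return cls(kind, quantizers=quantizers, bank_config=bank_config)

    def block_features(self, blocks) -> np.ndarray:
        if self.kind == "lbpc":
            return np.stack([lbp.lbpc_feature(b.window, self.quantizers)
                             for b in blocks])
        if self.kind == "haralick":
            return np.stack([haralick.haralick_feature(b.window) for b in blocks])
        return np.stack([gabor.gabor_feature(b.window, self._bank) for b in blocks])

    def resources_dict(self) -> dict:
        out: dict = {}
        if self.quantizers is not None:
            out["quantizers"] = [q.to_dict() for q in self.quantizers]
        if self.kind == "gabor":
            out["bank"] = self.bank_config.to_dict()
        return out

    @classmethod
    def from_model(cls, model: TrainedModel) -> "FeatureExtractor":
        quantizers = None
        if "quantizers" in model.resources:
            quantizers = [lbp.VarQuantizer.from_dict(d)
                          for d in model.resources["quantizers"]]
        bank_config = None
        if "bank" in model.resources:
            bank_config = gabor.GaborBankConfig.from_dict(model.resources["bank"])
        return cls(model.descriptor_kind, quantizers=quantizers,
                   bank_config=bank_config)


def _prep(img, cfg) -> tuple[np.ndarray, np.ndarray]:
    return preprocess.preprocess_image(
        img, cfg["scale_factor"], cfg["background_threshold"], cfg["morph_radius"])


def _blocks(gray, mask, cfg):
    return preprocess.extract_blocks(
        gray, mask, cfg["block_size"], cfg["stride"], cfg["min_tissue_fraction"])


def image_block_features(img, extractor: FeatureExtractor, cfg=None):
    """Preprocess one RGB image and return (features, blocks)."""
    cfg = {**DEFAULT_PREPROCESS, **(cfg or {})}
    gray, mask = _prep(img, cfg)
    blocks = _blocks(gray, mask, cfg)
    if not blocks:
        return np.empty((0, 0)), []
    return extractor.block_features(blocks), blocks


def train_model(images, labels, kind: str = "lbpc", C: float | None = None,
                cfg=None) -> TrainedModel:
    """Train a descriptor-specific linear SVM from labeled RGB images.

    Each image contributes all its tissue blocks, labeled with the image
    label.  ``C`` defaults to the descriptor's published cost parameter.
    """
    cfg = {**DEFAULT_PREPROCESS, **(cfg or {})}
    prepped = [_prep(img, cfg) for img in images]
    extractor = FeatureExtractor.fit(
        kind, [g for g, _ in prepped], [m for _, m in prepped])
    feats, block_labels = [], []
    for (gray, mask), label in zip(prepped, labels):
        blocks = _blocks(gray, mask, cfg)
        if not blocks:
            continue
        feats.append(extractor.block_features(blocks))
        block_labels.extend([label] * len(blocks))
    if not feats:
        raise ValueError("no tissue blocks found in the training images")
    X = np.vstack(feats)
    model = classify.train(X, block_labels, C=C if C is not None else DEFAULT_C[kind],
                           descriptor_kind=kind,
                           resources=extractor.resources_dict(), preprocess=cfg)
    return model


def predict_image(img, model: TrainedModel,
                  extractor: FeatureExtractor | None = None) -> ImageResult:
    """Classify one RGB image with a trained model."""
    extractor = extractor or FeatureExtractor.from_model(model)
    X, blocks = image_block_features(img, extractor, model.preprocess)
    if not blocks:
        raise BackgroundImageError(
            "image has no analyzable blocks (background only)")
    scores = model.decision_values(X)
    return classify.classify_image(scores, origins=[b.origin for b in blocks])


def segment_image(img, model: TrainedModel,
                  extractor: FeatureExtractor | None = None) -> ScoreMap:
    """Per-pixel score map of one RGB image (overlaps averaged)."""
    extractor = extractor or FeatureExtractor.from_model(model)
    cfg = {**DEFAULT_PREPROCESS, **(model.preprocess or {})}
    gray, mask = _prep(img, cfg)
    blocks = _blocks(gray, mask, cfg)
    if not blocks:
        return ScoreMap(values=np.zeros(gray.shape),
                        background=np.ones(gray.shape, dtype=bool))
    scores = model.decision_values(extractor.block_features(blocks))
    return score_map(gray.shape, [b.origin for b in blocks], scores,
                     block_size=cfg["block_size"])
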