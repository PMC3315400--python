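"""Linear C-SVM on block descriptors and image-level aggregation.

Blocks are classified independently by a linear support-vector machine
(L2-regularized hinge loss, LIBLINEAR-style); the signed decision value of
a block is its distance-scaled offset from the separating hyperplane, with
epithelium as the positive class.  An image is assigned the class of the
arithmetic mean of its block decision values; means outside [-1, 1] are
"strong" calls, those inside are "weak".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import LinearSVC

EPITHELIUM = "epithelium"
STROMA = "stroma"
CLASSES = (STROMA, EPITHELIUM)

#: Cost parameters selected per descriptor on the original validation set,
#: used when tuning is skipped.
DEFAULT_C = {"lbpc": 300.0, "haralick": 2048.0, "gabor": 2.0}

SVM_TOL = 1e-4
SVM_MAX_ITER = 200_000


class BackgroundImageError(ValueError):
    """Raised when an image has no tissue blocks and cannot be classified."""


def labels_to_signs(labels) -> np.ndarray:
    """Map class labels to -1 (stroma) / +1 (epithelium)."""
    out = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if lab == EPITHELIUM:
            out[i] = 1.0
        elif lab == STROMA:
            out[i] = -1.0
        else:
            raise ValueError(f"unknown label {lab!r}")
    return out


@dataclass
class TrainedModel:
    """A trained linear SVM plus everything needed to reapply it.

    ``weights`` and ``bias`` define the decision function ``w @ x + b``;
    ``resources`` carries descriptor state (VAR quantizer edges for lbpc,
    bank parameters for gabor) and ``preprocess`` the preprocessing
    configuration used at training time.
    """

    weights: np.ndarray
    bias: float
    C: float
    descriptor_kind: str
    resources: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model "
                f"({self.weights.shape[0]}, descriptor {self.descriptor_kind})")
        return X @ self.weights + self.bias

    def to_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "bias": self.bias, "C": self.C,
                "descriptor_kind": self.descriptor_kind,
                "resources": self.resources, "preprocess": self.preprocess}

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(weights=np.asarray(d["weights"], dtype=np.float64),
                   bias=float(d["bias"]), C=float(d["C"]),
                   descriptor_kind=d["descriptor_kind"],
                   resources=d.get("resources", {}),
                   preprocess=d.get("preprocess", {}))

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train(X: np.ndarray, labels, C: float, descriptor_kind: str = "lbpc",
          **model_kwargs) -> TrainedModel:
    """Fit the maximum-margin hyperplane at cost ``C``.

    Uses an L2-regularized hinge-loss linear SVM (the dual coordinate
    descent solver of LIBLINEAR), no class weighting and no feature
    standardization beyond the descriptors' own normalization.
    """
    X = np.asarray(X, dtype=np.float64)
    y = labels_to_signs(labels)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    svc = LinearSVC(C=C, loss="hinge", tol=SVM_TOL, max_iter=SVM_MAX_ITER,
                    random_state=0)
    svc.fit(X, y)
    return TrainedModel(weights=svc.coef_.ravel().copy(),
                        bias=float(svc.intercept_[0]), C=float(C),
                        descriptor_kind=descriptor_kind, **model_kwargs)


def tune_C(X_train, y_train, X_val, y_val,
           grid=tuple(2.0 ** k for k in range(21)),
           descriptor_kind: str = "lbpc"):
    """Select the cost parameter by block-level validation AUC.

    Trains one model per candidate ``C`` and scores the held-out blocks;
    returns ``(best_C, curve)`` where ``curve`` is a list of ``(C, auc)``
    pairs.  Ties are broken toward the smaller ``C``.
    """
    from .evaluate import roc_auc

    grid = list(grid)
    if not grid:
        raise ValueError("C grid must not be empty")
    curve = []
    for C in sorted(grid):
        model = train(X_train, y_train, C, descriptor_kind)
        scores = model.decision_values(X_val)
        auc = roc_auc(scores, y_val, ci=None)["auc"]
        curve.append((C, auc))
    best_C = max(curve, key=lambda t: (t[1], -t[0]))[0]
    return best_C, curve


@dataclass
class ImageResult:
    """Image-level classification from the mean block decision value."""

    mean_score: float
    predicted_class: str
    strength: str  # "strong" if |mean_score| > 1 else "weak"
    block_scores: list = field(default_factory=list)  # [(origin, score), ...]


def classify_image(block_scores, origins=None) -> ImageResult:
    """Aggregate block decision values into an image call.

    The mean score's sign decides the class (>= 0 -> epithelium, the
    decision threshold is zero); its magnitude decides the call strength
    (strictly greater than 1 -> strong).
    """
    scores = np.asarray(block_scores, dtype=np.float64)
    if scores.size == 0:
        raise BackgroundImageError(
            "image has no analyzable blocks (background only)")
    mean = float(scores.mean())
    cls = EPITHELIUM if mean >= 0 else STROMA
    strength = "strong" if abs(mean) > 1 else "weak"
    pairs = list(zip(origins, scores.tolist())) if origins is not None else []
    return ImageResult(mean_score=mean, predicted_class=cls,
                       strength=strength, block_scores=pairs)
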