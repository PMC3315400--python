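"""Evaluation statistics and pseudo-colored segmentation heat maps.

Image-level agreement with the reference labels is summarized by a 2x2
contingency table, percent agreement and Cohen's kappa; ranking accuracy by
the area under the ROC curve (Mann-Whitney estimator) with a DeLong or
bootstrap confidence interval.  The spatial output is a per-pixel score map
(block decision values averaged over overlaps) rendered through a diverging
blue-green-red colormap centered at zero.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import norm

from .classify import CLASSES, EPITHELIUM, STROMA


def _to_signs(labels) -> np.ndarray:
    """Accept string labels or +/-1 numerics; positive class = epithelium."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        return np.where(arr == EPITHELIUM, 1.0, -1.0)
    return np.where(np.asarray(arr, dtype=np.float64) > 0, 1.0, -1.0)


def contingency(truth, predictions) -> np.ndarray:
    """2x2 table, rows = truth, cols = prediction, order (stroma, epithelium)."""
    truth = list(truth)
    predictions = list(predictions)
    if len(truth) != len(predictions):
        raise ValueError("truth and prediction lengths differ")
    table = np.zeros((2, 2), dtype=np.int64)
    if not truth:
        warnings.warn("empty input: zero contingency table", stacklevel=2)
        return table
    idx = {c: i for i, c in enumerate(CLASSES)}
    for t, p in zip(truth, predictions):
        table[idx[t], idx[p]] += 1
    return table


def agreement_stats(table: np.ndarray) -> dict:
    """Agreement summary of a 2x2 contingency table.

    Returns percent agreement (diagonal share), Cohen's unweighted kappa
    ``(po - pe) / (1 - pe)``, the stroma sensitivity (stroma images called
    stroma), the stroma positive predictive value (stroma calls that are
    stroma), the conventional specificity with respect to stroma detection
    (epithelium images called epithelium), and the misclassified count.
    Kappa is undefined (NaN) when the chance agreement ``pe`` is 1.
    """
    t = np.asarray(table, dtype=np.float64)
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    po = np.trace(t) / n
    pe = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / n ** 2
    if pe >= 1.0:
        warnings.warn("degenerate marginals: kappa undefined", stacklevel=2)
        kappa = float("nan")
    else:
        kappa = (po - pe) / (1.0 - pe)
    stroma_truth = t[0].sum()
    stroma_pred = t[:, 0].sum()
    return {
        "percent_agreement": 100.0 * po,
        "kappa": kappa,
        "stroma_sensitivity": 100.0 * t[0, 0] / stroma_truth if stroma_truth else float("nan"),
        "stroma_ppv": 100.0 * t[0, 0] / stroma_pred if stroma_pred else float("nan"),
        "specificity": 100.0 * t[1, 1] / t[1].sum() if t[1].sum() else float("nan"),
        "misclassified": int(n - np.trace(t)),
        "n": int(n),
    }


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    # pair-counting estimator; ties count 1/2
    diff = pos[:, None] - neg[None, :]
    return float((np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0))
                 / (pos.size * neg.size))


def _delong_ci(pos, neg, auc, alpha=0.05):
    # DeLong structural components: per-observation placement values
    psi = (pos[:, None] > neg[None, :]).astype(np.float64)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = (np.var(v10, ddof=1) / pos.size if pos.size > 1 else 0.0) \
        + (np.var(v01, ddof=1) / neg.size if neg.size > 1 else 0.0)
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def roc_auc(scores, labels, ci="delong", n_boot=2000, seed=0, alpha=0.05) -> dict:
    """AUC by the Mann-Whitney pair-counting estimator.

    The AUC is the probability that a randomly chosen epithelium sample
    outscores a randomly chosen stroma sample (ties count one half).
    ``ci`` selects the confidence interval: "delong" (default), "bootstrap"
    (percentile, seeded), or None to skip.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = _to_signs(labels)
    pos, neg = scores[y > 0], scores[y < 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC requires both classes")
    auc = _auc_mann_whitney(pos, neg)
    out = {"auc": auc, "ci_low": None, "ci_high": None}
    if ci == "delong":
        out["ci_low"], out["ci_high"] = _delong_ci(pos, neg, auc, alpha)
    elif ci == "bootstrap":
        rng = np.random.default_rng(seed)
        stats = [
            _auc_mann_whitney(rng.choice(pos, pos.size), rng.choice(neg, neg.size))
            for _ in range(n_boot)
        ]
        out["ci_low"], out["ci_high"] = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    elif ci is not None:
        raise ValueError(f"unknown CI method {ci!r}")
    return out


class ScoreMap:
    """Per-pixel mean decision values with a background flag.

    Every pixel of each analyzed block receives that block's decision
    value; where blocks overlap, the values are averaged.  Pixels covered
    by no analyzed block are flagged background.
    """

    def __init__(self, values: np.ndarray, background: np.ndarray):
        self.values = values
        self.background = background


def score_map(shape: tuple[int, int], origins, scores,
              block_size: int = 80) -> ScoreMap:
    """Paint block decision values onto the analysis-scale pixel grid."""
    acc = np.zeros(shape, dtype=np.float64)
    cov = np.zeros(shape, dtype=np.int64)
    for (r, c), s in zip(origins, scores):
        acc[r:r + block_size, c:c + block_size] += s
        cov[r:r + block_size, c:c + block_size] += 1
    background = cov == 0
    values = np.zeros(shape)
    np.divide(acc, cov, out=values, where=~background)
    return ScoreMap(values=values, background=background)


def pseudo_color(smap: ScoreMap, clip: float | None = None,
                 background_color=(230, 230, 230)) -> np.ndarray:
    """Render a score map as an 8-bit RGB heat map.

    A diverging colormap maps large negative scores (stroma) to dark blue
    and large positives (epithelium) to dark red, through turquoise /
    light green (zero) / yellow / orange.  Scores are clipped symmetrically
    at ``clip`` (default: the 99th percentile of |score| over tissue);
    background pixels get a reserved neutral color.
    """
    from matplotlib import colormaps

    tissue = ~smap.background
    if clip is None:
        clip = float(np.percentile(np.abs(smap.values[tissue]), 99)) if tissue.any() else 1.0
    clip = max(clip, 1e-9)
    unit = (np.clip(smap.values, -clip, clip) + clip) / (2.0 * clip)
    rgba = colormaps["jet"](unit)
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    rgb[smap.background] = np.asarray(background_color, dtype=np.uint8)
    return rgb
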