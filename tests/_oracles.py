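"""Naive, independent reference implementations used only as test oracles."""

import numpy as np

from histotex.lbp import circle_offsets


def naive_lbp_var(gray, P, R):
    """Double-loop per-pixel LBP riu2 bins and VAR values.

    Bilinear interpolation and the riu2 mapping are re-derived from first
    principles (explicit corner weights, explicit rotation set) so this
    path shares no vectorized machinery with the production code.
    """
    gray = np.pad(np.asarray(gray, dtype=np.float64), ((0, 1), (0, 1)),
                  mode="edge")
    m = int(np.ceil(R))
    h, w = gray.shape[0] - 1, gray.shape[1] - 1
    offs = circle_offsets(P, R)
    bins = np.empty((h - 2 * m, w - 2 * m), dtype=np.int64)
    var = np.empty_like(bins, dtype=np.float64)
    for r in range(m, h - m):
        for c in range(m, w - m):
            center = gray[r, c]
            diffs = []
            for dr, dc in offs:
                r0, c0 = int(np.floor(dr)), int(np.floor(dc))
                tr, tc = dr - r0, dc - c0
                d = ((1 - tr) * (1 - tc) * (gray[r + r0, c + c0] - center)
                     + (1 - tr) * tc * (gray[r + r0, c + c0 + 1] - center)
                     + tr * (1 - tc) * (gray[r + r0 + 1, c + c0] - center)
                     + tr * tc * (gray[r + r0 + 1, c + c0 + 1] - center))
                diffs.append(d)
            code = sum(1 << k for k, d in enumerate(diffs) if d >= 0)
            bits = [(code >> k) & 1 for k in range(P)]
            trans = sum(bits[k] != bits[(k + 1) % P] for k in range(P))
            bins[r - m, c - m] = sum(bits) if trans <= 2 else P + 1
            mu = sum(diffs) / P
            var[r - m, c - m] = sum((d - mu) ** 2 for d in diffs) / P
    return bins, var


def naive_joint_hist(gray, P, R, quantizer):
    bins, var = naive_lbp_var(gray, P, R)
    hist = np.zeros((P + 2, quantizer.Q))
    for b, v in zip(bins.ravel(), var.ravel()):
        level = 0
        for e in quantizer.edges:
            if v >= e:
                level += 1
        hist[b, min(level, quantizer.Q - 1)] += 1
    return hist


def auc_trapezoid(scores, y_signs):
    """ROC area by explicit threshold sweep + trapezoidal integration."""
    scores = np.asarray(scores, dtype=np.float64)
    y = np.asarray(y_signs) > 0
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(y[order])
    fps = np.cumsum(~y[order])
    # collapse ties on score so each threshold appears once
    distinct = np.where(np.diff(scores[order]))[0]
    idx = np.r_[distinct, len(scores) - 1]
    tpr = np.r_[0, tps[idx]] / y.sum()
    fpr = np.r_[0, fps[idx]] / (~y).sum()
    return float(np.trapezoid(tpr, fpr))
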