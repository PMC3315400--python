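"""Gray-level co-occurrence matrices and the extended Haralick statistics.

Block luminances are linearly quantized to 8 gray levels; symmetric GLCMs
are accumulated for the offsets (0,1), (1,1) and (1,0) and normalized to
probability matrices.  Twenty second-order statistics (the classic Haralick
set plus the Soh-Tsatsoulis and Clausi extensions) are computed per offset
and concatenated into a 60-dimensional descriptor.
"""

from __future__ import annotations

import numpy as np

DEFAULT_LEVELS = 8
OFFSETS = ((0, 1), (1, 1), (1, 0))
_EPS = 1e-12

METRIC_NAMES = (
    "autocorrelation", "contrast", "correlation", "cluster_prominence",
    "cluster_shade", "dissimilarity", "energy", "entropy", "homogeneity",
    "maximum_probability", "sum_of_squares", "sum_average", "sum_variance",
    "sum_entropy", "difference_variance", "difference_entropy", "imc1",
    "imc2", "inverse_difference_normalized", "inverse_difference_moment_normalized",
)


def quantize_gray(window: np.ndarray, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Linearly quantize luminances in [0, 255] to integer levels.

    ``level = floor(value * levels / 256)``, clipped to ``[0, levels-1]``.
    """
    w = np.asarray(window, dtype=np.float64)
    return np.clip(np.floor(w * levels / 256.0), 0, levels - 1).astype(np.int64)


def glcm(levelgrid: np.ndarray, offset: tuple[int, int],
         levels: int = DEFAULT_LEVELS, mask: np.ndarray | None = None) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix at one offset.

    Counts every pair of levels separated by ``offset``, accumulated in
    both directions so the matrix equals its transpose, then normalizes to
    a probability matrix.  When a tissue ``mask`` is given, pairs with a
    background member are skipped.
    """
    g = np.asarray(levelgrid)
    dr, dc = offset
    h, w = g.shape
    if h <= abs(dr) or w <= abs(dc):
        raise ValueError(f"grid {h}x{w} too small for offset {offset}")
    a = g[max(0, -dr):h - max(0, dr), max(0, -dc):w - max(0, dc)]
    b = g[max(0, dr):h - max(0, -dr), max(0, dc):w - max(0, -dc)]
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        ma = m[max(0, -dr):h - max(0, dr), max(0, -dc):w - max(0, dc)]
        mb = m[max(0, dr):h - max(0, -dr), max(0, dc):w - max(0, -dc)]
        keep = ma & mb
        a, b = a[keep], b[keep]
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (a.ravel(), b.ravel()), 1.0)
    counts += counts.T  # symmetric accumulation
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs for GLCM")
    return counts / total


def glcm_metrics(p: np.ndarray) -> np.ndarray:
    """The 20 statistics of one normalized symmetric GLCM, in fixed order.

    Indices run 0..M-1.  Correlation with a zero-variance marginal is 0 by
    convention; entropies use base-2 logarithms with an epsilon guard.
    """
    p = np.asarray(p, dtype=np.float64)
    M = p.shape[0]
    i, j = np.mgrid[0:M, 0:M]
    px = p.sum(axis=1)
    mu_x = float(np.arange(M) @ px)
    sigma_x = float(np.sqrt(((np.arange(M) - mu_x) ** 2) @ px))
    # symmetric GLCM: both marginals identical
    mu_y, sigma_y = mu_x, sigma_x

    autocorrelation = float((i * j * p).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    if sigma_x > _EPS:
        correlation = (autocorrelation - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        correlation = 0.0
    dev = i + j - mu_x - mu_y
    cluster_prominence = float((dev ** 4 * p).sum())
    cluster_shade = float((dev ** 3 * p).sum())
    dissimilarity = float((np.abs(i - j) * p).sum())
    energy = float((p ** 2).sum())
    entropy = float(-(p * np.log2(p + _EPS)).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    maximum_probability = float(p.max())
    sum_of_squares = float(((i - mu_x) ** 2 * p).sum())

    # marginal distributions of i+j (0..2M-2) and |i-j| (0..M-1)
    p_sum = np.bincount((i + j).ravel(), weights=p.ravel(), minlength=2 * M - 1)
    p_diff = np.bincount(np.abs(i - j).ravel(), weights=p.ravel(), minlength=M)
    k_sum = np.arange(2 * M - 1)
    k_diff = np.arange(M)
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    sum_entropy = float(-(p_sum * np.log2(p_sum + _EPS)).sum())
    diff_mean = float(k_diff @ p_diff)
    difference_variance = float(((k_diff - diff_mean) ** 2) @ p_diff)
    difference_entropy = float(-(p_diff * np.log2(p_diff + _EPS)).sum())

    hx = float(-(px * np.log2(px + _EPS)).sum())
    hxy1 = float(-(p * np.log2(np.outer(px, px) + _EPS)).sum())
    hxy2 = float(-(np.outer(px, px) * np.log2(np.outer(px, px) + _EPS)).sum())
    denom = max(hx, _EPS)
    imc1 = (entropy - hxy1) / denom
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    idn = float((p / (1.0 + np.abs(i - j) / M)).sum())
    idmn = float((p / (1.0 + (i - j) ** 2 / M ** 2)).sum())

    return np.array([
        autocorrelation, contrast, correlation, cluster_prominence,
        cluster_shade, dissimilarity, energy, entropy, homogeneity,
        maximum_probability, sum_of_squares, sum_average, sum_variance,
        sum_entropy, difference_variance, difference_entropy, imc1, imc2,
        idn, idmn,
    ])


def haralick_feature(window: np.ndarray, levels: int = DEFAULT_LEVELS,
                     mask: np.ndarray | None = None,
                     offsets=OFFSETS) -> np.ndarray:
    """60-dimensional Haralick descriptor of one block.

    Quantizes the block, builds one symmetric GLCM per offset and
    concatenates the 20 statistics in offset order.
    """
    grid = quantize_gray(window, levels)
    return np.concatenate([glcm_metrics(glcm(grid, off, levels, mask))
                           for off in offsets])


def feature_names(offsets=OFFSETS) -> list[str]:
    """Column names metric_offset, e.g. ``contrast_01``."""
    return [f"{m}_{dr}{dc}" for (dr, dc) in offsets for m in METRIC_NAMES]
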