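"""Rotation-invariant uniform local binary patterns joined with local variance.

The LBP operator thresholds a circular neighborhood of ``P`` samples at
radius ``R`` against the center pixel and reads the resulting bits as a
base-2 number.  Uniform patterns (at most two 0/1 transitions around the
ring) are collapsed by circular-shift minimization into ``P + 1`` rotation
classes; all non-uniform patterns share one extra code, for ``P + 2`` codes
total ("riu2").  Because the pattern discards contrast, it is crossed with
the local variance (VAR) of the same circular samples, quantized into ``Q``
equal-mass levels learned from training data.  The block descriptor is the
concatenation of the (8,1) and (16,2) joint LBP/VAR histograms -- a
``(8+2)*8 + (16+2)*8 = 224``-bin vector scaled to unit Euclidean norm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

DEFAULT_Q = 8
#: The two operator configurations whose joint histograms are concatenated.
DEFAULT_CONFIGS = ((8, 1.0), (16, 2.0))
FEATURE_LENGTH = sum((p + 2) * DEFAULT_Q for p, _ in DEFAULT_CONFIGS)  # 224


@dataclass(frozen=True)
class LBPConfig:
    """Sampling geometry of one LBP/VAR operator: P points on radius R."""

    P: int = 8
    R: float = 1.0

    def __post_init__(self):
        if self.P < 4:
            raise ValueError("P must be at least 4")
        if self.R <= 0:
            raise ValueError("R must be positive")

    @property
    def margin(self) -> int:
        """Pixels near the edge lacking a full circular neighborhood."""
        return int(np.ceil(self.R))


def circle_offsets(P: int, R: float) -> np.ndarray:
    """(row, col) offsets of the P circular samples.

    Neighbor ``k`` sits at angle ``2*pi*k/P``, i.e. at offset
    ``(-R*sin, R*cos)`` in (row, col) convention, so neighbor 0 lies to the
    right of the center and the ring is traversed counter-clockwise.
    Near-integer coordinates are snapped to avoid spurious interpolation.
    """
    k = np.arange(P)
    angles = 2.0 * np.pi * k / P
    offs = np.stack([-R * np.sin(angles), R * np.cos(angles)], axis=1)
    snapped = np.round(offs)
    offs[np.abs(offs - snapped) < 1e-9] = snapped[np.abs(offs - snapped) < 1e-9]
    return offs


def lbp_code(center: float, neighbors) -> int:
    """Encode one neighborhood: bit ``k`` set iff ``neighbors[k] >= center``.

    Bits are weighted by powers of two (neighbor k contributes ``2**k``),
    so the binary code read with neighbor P-1 as the most significant digit
    is returned as its base-10 value.
    """
    code = 0
    for k, v in enumerate(neighbors):
        if v >= center:
            code |= 1 << k
    return code


def var_value(neighbors) -> float:
    """Local variance: population variance of the P circular samples.

    Uses the divide-by-P (population) convention; invariant to the order
    of the samples and to adding a constant to all of them.
    """
    return float(np.var(np.asarray(neighbors, dtype=np.float64)))


def rotate_min(code: int, P: int) -> int:
    """Minimum value of ``code`` over all circular bit shifts of length P."""
    full = (1 << P) - 1
    best = code
    for i in range(1, P):
        rotated = ((code >> i) | (code << (P - i))) & full
        if rotated < best:
            best = rotated
    return best


def transitions(code: int, P: int) -> int:
    """Number of 0/1 changes around the circular P-bit pattern."""
    rotated = ((code >> 1) | (code << (P - 1))) & ((1 << P) - 1)
    return bin(code ^ rotated).count("1")


def riu2_map(code: int, P: int) -> int:
    """Rotation-invariant uniform bin of an LBP code.

    Uniform codes (<= 2 circular transitions) minimize, under rotation, to
    ``2**k - 1`` where ``k`` is the number of set bits; their bin is that
    bit count, in ``[0, P]``.  Every non-uniform code maps to the single
    extra bin ``P + 1``.
    """
    if transitions(code, P) <= 2:
        return bin(code).count("1")
    return P + 1


@lru_cache(maxsize=None)
def _riu2_table(P: int) -> np.ndarray:
    return np.array([riu2_map(c, P) for c in range(1 << P)], dtype=np.int64)


def _ring_diffs(gray: np.ndarray, config: LBPConfig) -> np.ndarray:
    """Center-relative bilinear circular samples for every interior pixel.

    Returns an array of shape ``(P, H-2m, W-2m)`` holding, for each pixel
    with a full circular neighborhood, the interpolated neighbor value
    minus the center value.  Interpolating the *difference* (corner by
    corner) rather than the raw sample makes the subsequent threshold and
    variance exactly invariant to adding a constant to the whole image,
    which raw-sample interpolation cannot guarantee at floating precision.
    """
    gray = np.asarray(gray, dtype=np.float64)
    m = config.margin
    h, w = gray.shape
    if h < 2 * m + 1 or w < 2 * m + 1:
        raise ValueError(
            f"image {h}x{w} too small for radius {config.R} (needs {2 * m + 1} px per side)"
        )
    H, W = h - 2 * m, w - 2 * m
    center = gray[m:h - m, m:w - m]
    # pad bottom/right so the +1 corners exist even at integer offsets,
    # where their interpolation weight is exactly zero
    padded = np.pad(gray, ((0, 1), (0, 1)), mode="edge")
    diffs = np.empty((config.P, H, W))
    for k, (dr, dc) in enumerate(circle_offsets(config.P, config.R)):
        r0, c0 = int(np.floor(dr)), int(np.floor(dc))
        tr, tc = dr - r0, dc - c0
        g00 = padded[m + r0:m + r0 + H, m + c0:m + c0 + W]
        g01 = padded[m + r0:m + r0 + H, m + c0 + 1:m + c0 + 1 + W]
        g10 = padded[m + r0 + 1:m + r0 + 1 + H, m + c0:m + c0 + W]
        g11 = padded[m + r0 + 1:m + r0 + 1 + H, m + c0 + 1:m + c0 + 1 + W]
        diffs[k] = ((1 - tr) * (1 - tc) * (g00 - center)
                    + (1 - tr) * tc * (g01 - center)
                    + tr * (1 - tc) * (g10 - center)
                    + tr * tc * (g11 - center))
    return diffs


def lbp_var_grids(gray: np.ndarray, config: LBPConfig):
    """Per-pixel riu2 bin and VAR value over the valid interior.

    Bit ``k`` of a pixel's code is set iff the interpolated neighbor is >=
    the center; VAR is the population variance (divide by P) of the P
    circular samples.
    """
    diffs = _ring_diffs(gray, config)
    bits = (diffs >= 0).astype(np.int64)
    weights = (1 << np.arange(config.P, dtype=np.int64))[:, None, None]
    codes = (bits * weights).sum(axis=0)
    bins = _riu2_table(config.P)[codes]
    mu = diffs.mean(axis=0)
    var = ((diffs - mu) ** 2).mean(axis=0)
    return bins, var


@dataclass
class VarQuantizer:
    """Equal-mass quantizer of VAR values trained on a set of images.

    ``edges`` are the ``i/Q`` empirical quantiles (i = 1..Q-1) of pooled
    per-pixel VAR values; quantization assigns level = number of edges
    <= value (half-open bins: equality goes to the higher level), clipped
    to ``[0, Q-1]``.
    """

    Q: int
    edges: np.ndarray
    config: LBPConfig

    def quantize(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values)
        return np.clip(np.searchsorted(self.edges, v, side="right"), 0, self.Q - 1)

    def to_dict(self) -> dict:
        return {"Q": self.Q, "edges": np.asarray(self.edges).tolist(),
                "P": self.config.P, "R": self.config.R}

    @classmethod
    def from_dict(cls, d: dict) -> "VarQuantizer":
        return cls(Q=int(d["Q"]), edges=np.asarray(d["edges"], dtype=np.float64),
                   config=LBPConfig(int(d["P"]), float(d["R"])))

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "VarQuantizer":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_var_quantizer(
    images,
    config: LBPConfig,
    Q: int = DEFAULT_Q,
    masks=None,
) -> VarQuantizer:
    """Learn VAR quantization edges from training images.

    Pools per-pixel VAR values over all images (restricted to tissue pixels
    when ``masks`` are given), and places cut points at the ``i/Q``
    quantiles so each level holds an equal share of training pixels.
    Duplicate edges from a degenerate distribution are collapsed with a
    warning.
    """
    pooled = []
    for i, img in enumerate(images):
        _, var = lbp_var_grids(img, config)
        if masks is not None:
            m = config.margin
            mask = np.asarray(masks[i], dtype=bool)[m:-m or None, m:-m or None]
            var = var[mask]
        pooled.append(np.ravel(var))
    pooled = np.concatenate(pooled)
    if pooled.size == 0:
        raise ValueError("no pixels available to train the quantizer")
    edges = np.quantile(pooled, np.arange(1, Q) / Q)
    unique = np.unique(edges)
    if unique.size < Q - 1:
        warnings.warn(
            f"degenerate VAR distribution: only {unique.size + 1} usable levels of {Q}",
            stacklevel=2,
        )
        edges = unique
    return VarQuantizer(Q=Q, edges=np.asarray(edges, dtype=np.float64), config=config)


def joint_histogram(window: np.ndarray, quantizer: VarQuantizer) -> np.ndarray:
    """(P+2) x Q joint count matrix of (riu2 bin, VAR level) over a block.

    Every pixel with a full circular neighborhood inside the window
    contributes one count.  The matrix flattens row-major (LBP bin major,
    VAR level minor) into the feature vector.
    """
    config = quantizer.config
    bins, var = lbp_var_grids(window, config)
    levels = quantizer.quantize(var)
    flat = bins.ravel() * quantizer.Q + levels.ravel()
    counts = np.bincount(flat, minlength=(config.P + 2) * quantizer.Q)
    return counts.reshape(config.P + 2, quantizer.Q).astype(np.float64)


def lbpc_feature(window: np.ndarray, quantizers) -> np.ndarray:
    """Unit-norm 224-bin LBP/C descriptor of one block.

    Concatenates the flattened joint histograms of every configured
    operator (default (8,1) then (16,2): 80 + 144 = 224 bins) and scales
    the result to unit Euclidean norm.
    """
    parts = [joint_histogram(window, q).ravel() for q in quantizers]
    v = np.concatenate(parts)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("empty joint histogram: block has no valid pixels")
    return v / norm


def train_default_quantizers(images, masks=None, Q: int = DEFAULT_Q) -> list[VarQuantizer]:
    """Train the (8,1) and (16,2) VAR quantizers on one image set."""
    return [train_var_quantizer(images, LBPConfig(p, r), Q=Q, masks=masks)
            for p, r in DEFAULT_CONFIGS]
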