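"""Preprocessing: grayscale conversion, downscaling, tissue masking, block extraction.

The analysis representation of a histology image is a downscaled grayscale
grid together with a binary tissue mask. Feature extraction operates on
overlapping square blocks slid over the image; blocks with too little tissue
under the mask are discarded as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import closing, disk, erosion
from skimage.transform import resize

# Luminance weights of the ITU-R 601 standard used for RGB -> gray.
GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)

DEFAULT_SCALE = 0.5
DEFAULT_BACKGROUND_THRESHOLD = 240.0
DEFAULT_MORPH_RADIUS = 5
DEFAULT_BLOCK_SIZE = 80
DEFAULT_STRIDE = 40
DEFAULT_MIN_TISSUE = 0.5


@dataclass
class Block:
    """An analysis window of a grayscale image.

    Attributes
    ----------
    window : ndarray
        Square luminance grid (floating point, values in [0, 255]).
    origin : tuple of int
        (row, col) of the top-left pixel, 0-based, in the analysis-scale image.
    tissue_fraction : float
        Fraction of window pixels flagged as tissue by the mask.
    mask : ndarray or None
        Boolean tissue mask aligned to the window (None means all tissue).
    """

    window: np.ndarray
    origin: tuple[int, int]
    tissue_fraction: float
    mask: np.ndarray | None = field(default=None, repr=False)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to floating-point luminance.

    Each output pixel is ``0.2989*R + 0.5870*G + 0.1140*B``.  Grayscale
    input (2-D) is passed through as float.  Values are kept at floating
    precision; quantization is left to the individual descriptors.
    """
    a = np.asarray(img)
    if a.ndim == 2:
        return a.astype(np.float64)
    if a.ndim != 3 or a.shape[2] not in (3, 4):
        raise ValueError(f"expected HxWx3 RGB input, got shape {a.shape}")
    r, g, b = (a[..., i].astype(np.float64) for i in range(3))
    wr, wg, wb = GRAY_WEIGHTS
    return wr * r + wg * g + wb * b


def downscale(img: np.ndarray, factor: float = DEFAULT_SCALE) -> np.ndarray:
    """Rescale an image by ``factor`` with bilinear interpolation.

    Output dimensions are ``floor(input * factor)``.  Works on both color
    (HxWx3) and grayscale (HxW) arrays; ``factor=1`` returns the input
    unchanged.
    """
    if factor <= 0 or factor > 1:
        raise ValueError(f"scale factor must be in (0, 1], got {factor}")
    a = np.asarray(img)
    if factor == 1.0:
        return a
    h = int(np.floor(a.shape[0] * factor))
    w = int(np.floor(a.shape[1] * factor))
    out_shape = (h, w) + a.shape[2:]
    out = resize(a.astype(np.float64), out_shape, order=1, mode="reflect",
                 anti_aliasing=False, preserve_range=True)
    return out


def compute_tissue_mask(
    gray: np.ndarray,
    threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
    morph_radius: int = DEFAULT_MORPH_RADIUS,
) -> np.ndarray:
    """Binary tissue mask of a grayscale image.

    Bright-field background has high luminance: pixels with luminance >=
    ``threshold`` are background (0), the rest tissue (1).  The raw mask is
    then smoothed by morphological closing followed by erosion with a disk
    structuring element of ``morph_radius`` pixels.
    """
    gray = np.asarray(gray, dtype=np.float64)
    mask = gray < threshold
    if morph_radius > 0:
        selem = disk(morph_radius)
        mask = closing(mask, selem)
        mask = erosion(mask, selem)
    return mask.astype(np.uint8)


def extract_blocks(
    gray: np.ndarray,
    mask: np.ndarray | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
    stride: int = DEFAULT_STRIDE,
    min_tissue: float = DEFAULT_MIN_TISSUE,
) -> list[Block]:
    """Slide a square window over the image and keep tissue-rich blocks.

    Windows start at the upper-left corner and move row by row with step
    ``stride`` (half a block by default, giving 50% overlap).  Windows that
    would extend past the image edge are dropped.  A block is emitted iff
    the mask covers at least ``min_tissue`` of its area.
    """
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    if mask is None:
        mask = np.ones((h, w), dtype=np.uint8)
    mask = np.asarray(mask)
    if mask.shape != gray.shape:
        raise ValueError("mask dimensions must match the image")
    if h < block_size or w < block_size:
        warnings.warn(
            f"image ({h}x{w}) smaller than one {block_size}px block; no blocks emitted",
            stacklevel=2,
        )
        return []
    blocks: list[Block] = []
    area = float(block_size * block_size)
    for r in range(0, h - block_size + 1, stride):
        for c in range(0, w - block_size + 1, stride):
            m = mask[r:r + block_size, c:c + block_size]
            frac = float(np.count_nonzero(m)) / area
            if frac >= min_tissue:
                blocks.append(Block(
                    window=gray[r:r + block_size, c:c + block_size],
                    origin=(r, c),
                    tissue_fraction=frac,
                    mask=m.astype(bool),
                ))
    return blocks


def preprocess_image(
    img: np.ndarray,
    scale_factor: float = DEFAULT_SCALE,
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
    morph_radius: int = DEFAULT_MORPH_RADIUS,
) -> tuple[np.ndarray, np.ndarray]:
    """Full preprocessing chain: scale -> grayscale -> tissue mask.

    Scaling is applied to the color image first, then grayscale conversion,
    then background removal.  Returns ``(gray, mask)`` at analysis scale.
    """
    scaled = downscale(img, scale_factor)
    gray = to_grayscale(scaled)
    mask = compute_tissue_mask(gray, background_threshold, morph_radius)
    return gray, mask
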