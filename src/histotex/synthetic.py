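"""Deterministic two-class synthetic textures for end-to-end testing.

Real epithelium shows rounded, blob-like nuclear clusters on a pale
background while stroma is dominated by oriented collagen fibers.  The
generator emulates exactly that contrast in second-order statistics:

* ``blob`` ("epithelium-like"): a smoothed random point process whose
  bumps read as dark rounded clusters on a pale background;
* ``fiber`` ("stroma-like"): oriented band-pass noise producing elongated
  streaks along a controllable orientation.

Brightness, contrast and rotation perturbations are applied last so
photometric-invariance claims can be exercised.  The same spec always
produces a bit-identical image.  These are statistical stand-ins: they do
not reproduce staining variation, nuclear morphology or scanner artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

MIN_SIZE = 80  # must fit one analysis block

#: Mild per-channel tints so fixtures resemble hematoxylin/eosin tones.
_TINTS = {"blob": (0.88, 0.80, 0.98), "fiber": (1.00, 0.86, 0.92)}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic texture image."""

    class_kind: str  # "blob" | "fiber"
    size: int = 160
    seed: int = 0
    blob_density: float = 0.01  # points per pixel before smoothing
    blob_sigma: float = 4.0  # px, bump radius
    fiber_orientation: float = 0.0  # degrees
    fiber_width: float = 2.0  # px, streak thickness
    fiber_length: float = 12.0  # px, streak elongation
    brightness_offset: float = 0.0
    contrast_gain: float = 1.0
    rotation: float = 0.0  # degrees, applied to the finished texture
    difficulty: float = 0.0  # 0 = well separated, 1 = heavily blurred classes

    def __post_init__(self):
        if self.class_kind not in ("blob", "fiber"):
            raise ValueError(f"unknown class kind {self.class_kind!r}")
        if self.size < MIN_SIZE:
            raise ValueError(f"size must be >= {MIN_SIZE}, got {self.size}")


def _normalize(field: np.ndarray) -> np.ndarray:
    field = field - field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def _blob_texture(rng, canvas: int, spec: SyntheticSpec) -> np.ndarray:
    impulses = (rng.random((canvas, canvas)) < spec.blob_density).astype(np.float64)
    bumps = ndimage.gaussian_filter(impulses, spec.blob_sigma, mode="wrap")
    bumps = _normalize(bumps)
    # rounded dark clusters on a paler background; luminance kept well
    # inside [0, 255] so photometric perturbations do not clip
    gray = 170.0 - 45.0 * np.clip(bumps, -1.0, 3.0)
    return gray


def _fiber_texture(rng, canvas: int, spec: SyntheticSpec) -> np.ndarray:
    noise = rng.standard_normal((canvas, canvas))
    # anisotropic smoothing: long axis along rows, then rotate into place
    streaks = ndimage.gaussian_filter(
        noise, sigma=(spec.fiber_width, spec.fiber_length), mode="wrap")
    if spec.fiber_orientation:
        streaks = ndimage.rotate(streaks, spec.fiber_orientation,
                                 reshape=False, order=1, mode="reflect")
    streaks = _normalize(streaks)
    gray = 165.0 - 35.0 * np.clip(streaks, -2.2, 2.2)
    return gray


def generate_gray(spec: SyntheticSpec) -> np.ndarray:
    """Grayscale texture per spec, deterministic in the seed."""
    rng = np.random.default_rng(spec.seed)
    margin = int(np.ceil(spec.size * 0.25))
    canvas = spec.size + 2 * margin
    if spec.class_kind == "blob":
        gray = _blob_texture(rng, canvas, spec)
    else:
        gray = _fiber_texture(rng, canvas, spec)
    if spec.difficulty > 0:
        # blur class identity toward a common isotropic texture
        common = _normalize(ndimage.gaussian_filter(
            rng.standard_normal((canvas, canvas)), 3.0, mode="wrap"))
        gray = (1 - spec.difficulty) * gray \
            + spec.difficulty * (168.0 - 40.0 * np.clip(common, -2.5, 2.5))
    gray = gray + 4.0 * rng.standard_normal((canvas, canvas))  # sensor noise
    if spec.rotation:
        gray = ndimage.rotate(gray, spec.rotation, reshape=False,
                              order=1, mode="reflect")
    gray = gray[margin:margin + spec.size, margin:margin + spec.size]
    gray = gray * spec.contrast_gain + spec.brightness_offset
    return np.clip(gray, 0.0, 255.0)


def generate(spec: SyntheticSpec) -> np.ndarray:
    """8-bit RGB texture image (grayscale texture under a faint H&E tint)."""
    gray = generate_gray(spec)
    tint = _TINTS[spec.class_kind]
    rgb = np.stack([gray * t for t in tint], axis=-1)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def _split_counts(n: int, ratios) -> list[int]:
    """Per-class split sizes: round the first splits, remainder to the last."""
    counts = [int(np.floor(n * r + 0.5)) for r in ratios[:-1]]
    counts.append(n - sum(counts))
    if any(c < 0 for c in counts):
        raise ValueError(f"ratios {ratios} infeasible for n={n}")
    return counts


def generate_dataset(n_per_class: int, ratios=(0.5, 0.25, 0.25), seed: int = 0,
                     size: int = 160, difficulty: float = 0.0) -> dict:
    """Seeded, disjoint train/validation/test image sets for both classes.

    ``n_per_class`` is the total per class across the three splits.  Every
    image gets a unique derived seed (no overlap across splits), a random
    orientation/rotation, and mild photometric jitter so the classes are
    not separable by brightness alone.  Returns
    ``{split: [(image, label, spec), ...]}`` with labels "epithelium"
    (blob) and "stroma" (fiber).
    """
    master = np.random.default_rng(seed)
    splits = ("train", "validation", "test")
    counts = _split_counts(n_per_class, ratios)
    out: dict[str, list] = {s: [] for s in splits}
    counter = 0
    for split, count in zip(splits, counts):
        for kind, label in (("blob", "epithelium"), ("fiber", "stroma")):
            for _ in range(count):
                img_seed = int((seed * 100003 + counter) % (2**31 - 1))
                counter += 1
                spec = SyntheticSpec(
                    class_kind=kind, size=size, seed=img_seed,
                    fiber_orientation=float(master.uniform(0, 180)),
                    rotation=float(master.choice([0.0, 90.0, 180.0, 270.0])),
                    brightness_offset=float(master.uniform(-10, 10)),
                    contrast_gain=float(master.uniform(0.95, 1.05)),
                    difficulty=difficulty,
                )
                out[split].append((generate(spec), label, spec))
    return out
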