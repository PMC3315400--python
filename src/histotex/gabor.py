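"""Gabor filter-bank descriptor: mean and std of response magnitudes.

The bank spans 6 orientations (theta = n*pi/6, n = 0..5) and 4 scales
(s = 0..3).  Frequencies follow octave spacing from a base frequency, in
the Manjunath-Ma style: ``f_s = base / 2**s``.  Each complex filter is
DC-corrected so constant regions respond with zero; the block descriptor
is the mean and standard deviation of the complex response magnitude for
each of the 24 filters, 48 values total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel


@dataclass(frozen=True)
class GaborBankConfig:
    n_orientations: int = 6
    n_scales: int = 4
    base_frequency: float = 0.25  # cycles/px at scale 0
    frequency_ratio: float = 2.0  # divisor per scale step (octave spacing)
    bandwidth: float = 1.0  # octaves

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(self.base_frequency / self.frequency_ratio ** s
                     for s in range(self.n_scales))

    @property
    def orientations(self) -> tuple[float, ...]:
        return tuple(np.pi * n / self.n_orientations
                     for n in range(self.n_orientations))

    def to_dict(self) -> dict:
        return {"n_orientations": self.n_orientations, "n_scales": self.n_scales,
                "base_frequency": self.base_frequency,
                "frequency_ratio": self.frequency_ratio, "bandwidth": self.bandwidth}

    @classmethod
    def from_dict(cls, d: dict) -> "GaborBankConfig":
        return cls(**d)


def build_bank(config: GaborBankConfig = GaborBankConfig()) -> list[np.ndarray]:
    """Complex kernels in fixed enumeration order (scale-major, theta-minor).

    Each kernel is DC-corrected by subtracting a Gaussian-weighted offset
    from its real part so the kernel sums to (approximately) zero.
    """
    if config.base_frequency > 0.5:
        raise ValueError(
            f"base frequency {config.base_frequency} exceeds Nyquist (0.5 cycles/px)")
    kernels = []
    for f in config.frequencies:
        for theta in config.orientations:
            k = gabor_kernel(frequency=f, theta=theta,
                             bandwidth=config.bandwidth).astype(np.complex128)
            envelope = np.abs(k)
            k = k - (k.real.sum() / envelope.sum()) * envelope
            kernels.append(k)
    return kernels


def gabor_feature(window: np.ndarray, bank: list[np.ndarray]) -> np.ndarray:
    """Mean and std of response magnitude per filter, concatenated.

    Convolution uses reflect padding; statistics are taken over the full
    block.  Layout: [mean_0, std_0, mean_1, std_1, ...] in bank order.
    """
    w = np.asarray(window, dtype=np.float64)
    out = np.empty(2 * len(bank))
    for idx, k in enumerate(bank):
        ph, pw = k.shape[0] // 2, k.shape[1] // 2
        padded = np.pad(w, ((ph, ph), (pw, pw)), mode="reflect")
        resp = fftconvolve(padded, k, mode="same")
        mag = np.abs(resp[ph:ph + w.shape[0], pw:pw + w.shape[1]])
        out[2 * idx] = mag.mean()
        out[2 * idx + 1] = mag.std()
    return out
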