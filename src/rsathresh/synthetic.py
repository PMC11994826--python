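"""Synthetic images and histograms with known structure.

The generators emulate the *statistical* shape the thresholding methods
assume — multimodal intensity histograms — rather than the pixel content
of any benchmark or clinical image set: a Gaussian-mixture sampler for
multimodal images, a delta histogram for exact point masses, and an
intensity ramp whose histogram is exactly uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histograms import N_LEVELS, ChannelHistogram


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian intensity mixture: (mean, std, weight) modes + image shape."""

    modes: tuple[tuple[float, float, float], ...]
    shape: tuple[int, int] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modes:
            raise ValueError("need at least one mode")
        w = sum(m[2] for m in self.modes)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mode weights must sum to 1, got {w}")
        for mean, std, _ in self.modes:
            if not 0 <= mean <= N_LEVELS - 1:
                raise ValueError(f"mode mean {mean} outside [0, 255]")
            if std <= 0:
                raise ValueError("mode std must be positive")


def gaussian_mixture_image(spec: MixtureSpec) -> np.ndarray:
    """Sample every pixel from the mixture; round and clip to [0, 255]."""
    rng = np.random.default_rng(spec.seed)
    n = spec.shape[0] * spec.shape[1]
    weights = np.asarray([m[2] for m in spec.modes])
    comp = rng.choice(len(spec.modes), size=n, p=weights)
    means = np.asarray([m[0] for m in spec.modes])[comp]
    stds = np.asarray([m[1] for m in spec.modes])[comp]
    vals = rng.normal(means, stds)
    img = np.clip(np.round(vals), 0, N_LEVELS - 1).astype(np.uint8)
    return img.reshape(spec.shape)


def gaussian_mixture_histogram(spec: MixtureSpec) -> ChannelHistogram:
    """Histogram of a sampled mixture image."""
    img = gaussian_mixture_image(spec)
    counts = np.bincount(img.ravel(), minlength=N_LEVELS)
    return ChannelHistogram(counts)


def delta_histogram(
    levels: list[int], weights: list[float], total: int = 1000
) -> ChannelHistogram:
    """Point-mass histogram: counts ∝ weights at ``levels``, zero elsewhere."""
    levels = [int(v) for v in levels]
    if any(v < 0 or v > N_LEVELS - 1 for v in levels):
        raise ValueError(f"levels must lie in [0, {N_LEVELS - 1}]")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    counts = np.zeros(N_LEVELS, dtype=np.int64)
    raw = w * total
    for lv, c in zip(levels, np.round(raw).astype(int)):
        counts[lv] += max(int(c), 0)
    return ChannelHistogram(counts)


def ramp_image(shape: tuple[int, int] = (4, 256)) -> np.ndarray:
    """Left-to-right intensity ramp covering 0..255.

    With a width that is a multiple of 256 the histogram is exactly
    uniform (``Q = 256`` gives one pixel per level per row).
    """
    m, q = shape
    if m < 1 or q < 1:
        raise ValueError("shape must be positive")
    row = np.floor(np.arange(q) * N_LEVELS / q).astype(np.uint8)
    return np.tile(row, (m, 1))
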