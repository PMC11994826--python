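"""Segmented-image reconstruction and quality measures (RMSE, PSNR, SSIM).

``apply_thresholds`` labels each pixel by the half-open class rule and
rebuilds a "segmented image" whose pixels carry their class's mean
intensity — the reconstruction that minimizes RMSE and makes the variance
identity ``RMSE² = total variance − σ_B`` exact at the Otsu optimum.

PSNR is ``20·log10(255/RMSE)`` in dB (``+inf`` for a perfect match); SSIM
is the single-window global form with stabilizing constants
``C1 = 6.5025`` and ``C2 = 58.52252`` and population (1/N) variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histograms import validate_image
from .objectives import ThresholdVector, partition_levels

SSIM_C1 = 6.5025
SSIM_C2 = 58.52252


@dataclass(frozen=True)
class SegmentationResult:
    """Pixel label map plus the class-mean reconstruction."""

    labels: np.ndarray          # class index per pixel, in [0, m−1]
    reconstruction: np.ndarray  # uint8 class-representative image
    thresholds: ThresholdVector
    class_means: np.ndarray     # representative intensity per class


def apply_thresholds(img: np.ndarray, t: ThresholdVector) -> SegmentationResult:
    """Segment a single-channel image with thresholds ``t``.

    Each pixel's class representative is the mean intensity of its class in
    this image (rounded to the nearest integer); classes with no pixels get
    the midpoint of their gray-level interval.
    """
    img = validate_image(img)
    if img.ndim != 2:
        raise ValueError("apply_thresholds expects a single-channel image")
    level_class = partition_levels(t)
    labels = level_class[img]
    m = t.class_count
    edges = [0, *t.values, 256]
    means = np.empty(m)
    flat = img.ravel().astype(np.float64)
    lab_flat = labels.ravel()
    counts = np.bincount(lab_flat, minlength=m)
    sums = np.bincount(lab_flat, weights=flat, minlength=m)
    for i in range(m):
        if counts[i] > 0:
            means[i] = round(sums[i] / counts[i])
        else:
            means[i] = round((edges[i] + edges[i + 1] - 1) / 2)
    recon = means[labels].astype(np.uint8)
    return SegmentationResult(labels, recon, t, means)


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a, b = validate_image(a), validate_image(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a.astype(np.float64), b.astype(np.float64)


def rmse(original: np.ndarray, segmented: np.ndarray) -> float:
    """Root-mean-squared intensity difference over the M×Q pixels."""
    a, b = _check_pair(original, segmented)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(original: np.ndarray, segmented: np.ndarray) -> float:
    """Peak signal-to-noise ratio 20·log10(255/RMSE) in dB (inf if equal)."""
    r = rmse(original, segmented)
    if r == 0.0:
        return float("inf")
    return float(20.0 * np.log10(255.0 / r))


def ssim(original: np.ndarray, segmented: np.ndarray) -> float:
    """Global (single-window) structural similarity index.

    Uses whole-image means, population variances and covariance with the
    fixed constants C1 = 6.5025, C2 = 58.52252; 1 means identical images.
    """
    a, b = _check_pair(original, segmented)
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    num = (2 * mu_a * mu_b + SSIM_C1) * (2 * cov + SSIM_C2)
    den = (mu_a**2 + mu_b**2 + SSIM_C1) * (var_a + var_b + SSIM_C2)
    return float(num / den)


@dataclass(frozen=True)
class MetricReport:
    rmse: float
    psnr: float
    ssim: float


def evaluate_segmentation(img: np.ndarray, seg: SegmentationResult) -> MetricReport:
    """RMSE/PSNR/SSIM of a reconstruction against its source channel."""
    rec = seg.reconstruction
    return MetricReport(rmse(img, rec), psnr(img, rec), ssim(img, rec))
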