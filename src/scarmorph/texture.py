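"""Histogram and gray-level co-occurrence (GLCM) texture features.

Six first-order statistics come from the normalized intensity histogram
(mean, standard deviation, smoothness, skewness, uniformity, entropy) — they
see only the gray-level distribution, not pixel positions.  Four second-order
Haralick statistics (contrast, correlation, energy, homogeneity) come from a
symmetric GLCM summed over the four unit-distance directions, and so carry
neighborhood information the histogram cannot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .errors import ParameterError
from .images import ChannelImage

DEFAULT_GLCM_ANGLES_DEG = (0.0, 45.0, 90.0, 135.0)


@dataclass(frozen=True)
class HistogramFeatures:
    mean_intensity: float
    std_intensity: float
    smoothness: float
    skewness: float
    uniformity: float
    entropy_bits: float


@dataclass(frozen=True)
class GLCMFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float


def histogram_features(img: ChannelImage) -> HistogramFeatures:
    """First-order statistics of the gray-level histogram.

    With p(z_i) the normalized histogram over L = 2**bit_depth levels:
    mean m = sum z_i p(z_i); std s = sqrt(sum (z_i-m)^2 p(z_i));
    smoothness R = 1 - 1/(1 + (s/(L-1))^2) (normalized so R < 1 at any bit
    depth); skewness = standardized third moment (0 when s = 0);
    uniformity U = sum p^2; entropy = -sum p log2 p in bits.
    """
    levels = 2 ** img.bit_depth
    counts = np.bincount(img.pixels.ravel(), minlength=levels)
    p = counts / counts.sum()
    z = np.arange(levels, dtype=float)
    m = float(np.sum(z * p))
    var = float(np.sum((z - m) ** 2 * p))
    s = np.sqrt(var)
    sn = s / (levels - 1)
    smooth = 1.0 - 1.0 / (1.0 + sn * sn)
    skew = float(np.sum(((z - m) / s) ** 3 * p)) if s > 0 else 0.0
    uniformity = float(np.sum(p * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return HistogramFeatures(mean_intensity=m, std_intensity=s,
                             smoothness=smooth, skewness=skew,
                             uniformity=uniformity, entropy_bits=entropy)


def quantize(img: ChannelImage, levels: int) -> np.ndarray:
    """Linearly map [0, 2**bit_depth) onto integer codes [0, levels)."""
    if levels < 2:
        raise ParameterError("levels must be >= 2")
    if levels > 2 ** img.bit_depth:
        raise ParameterError(
            f"levels={levels} exceeds the {img.bit_depth}-bit gray range")
    codes = (img.pixels.astype(np.int64) * levels) // (2 ** img.bit_depth)
    return codes.astype(np.uint16 if levels > 256 else np.uint8)


def glcm(img: ChannelImage, levels: int = 8, distance: int = 1,
         angles_deg=DEFAULT_GLCM_ANGLES_DEG) -> np.ndarray:
    """Normalized symmetric co-occurrence table.

    Counts are accumulated for each direction and its opposite (symmetric),
    summed over the requested directions (default: the four standard
    unit-distance offsets at 0/45/90/135 degrees), then normalized to total
    mass 1.
    """
    if distance < 1:
        raise ParameterError("distance must be >= 1")
    if not len(angles_deg):
        raise ParameterError("at least one offset direction is required")
    q = quantize(img, levels)
    mats = graycomatrix(q, distances=[distance],
                        angles=np.deg2rad(angles_deg), levels=levels,
                        symmetric=True, normed=False)
    table = mats[:, :, 0, :].sum(axis=-1).astype(float)
    total = table.sum()
    if total == 0:
        raise ParameterError("image too small for the requested GLCM offsets")
    return table / total


def glcm_features(table: np.ndarray) -> GLCMFeatures:
    """Contrast, correlation, energy and homogeneity of a normalized GLCM.

    correlation is defined as 1 for a degenerate table whose marginal
    standard deviations vanish (a constant image co-occurs only with itself).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ParameterError("GLCM table must be square")
    if abs(table.sum() - 1.0) > 1e-8:
        raise ParameterError("GLCM table must be normalized to sum 1")
    n = table.shape[0]
    i, j = np.indices((n, n))
    contrast = float(np.sum((i - j) ** 2 * table))
    p_i = table.sum(axis=1)
    p_j = table.sum(axis=0)
    mu_i = float(np.sum(np.arange(n) * p_i))
    mu_j = float(np.sum(np.arange(n) * p_j))
    sd_i = np.sqrt(float(np.sum((np.arange(n) - mu_i) ** 2 * p_i)))
    sd_j = np.sqrt(float(np.sum((np.arange(n) - mu_j) ** 2 * p_j)))
    if sd_i * sd_j == 0:
        correlation = 1.0
    else:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * table)
                            / (sd_i * sd_j))
    energy = float(np.sum(table ** 2))
    homogeneity = float(np.sum(table / (1.0 + np.abs(i - j))))
    return GLCMFeatures(contrast=contrast, correlation=correlation,
                        energy=energy, homogeneity=homogeneity)
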