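"""Gray-level co-occurrence (spatial dependence) matrix features.

For each configured angle a symmetric, normalized co-occurrence matrix is
accumulated at the configured pixel distance; the 13 classic second-order
statistics are computed per angle and averaged over angles.  Logarithms are
base 2; correlation is defined as 0 when either marginal is degenerate.
"""

from __future__ import annotations

from typing import Iterable, Tuple

import numpy as np

NAMES = (
    "Correlation",
    "Difference of entropy",
    "Difference of variance",
    "Sum of average",
    "Sum of entropy",
    "Sum of squares",
    "Sum of variance",
    "Contrast",
    "Energy",
    "Entropy",
    "Local homogeneity",
    "Cluster shade",
    "Cluster prominence",
)

#: offset (drow, dcol) per angle in degrees, unit distance
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def cooccurrence_matrix(
    pixels: np.ndarray, levels: int, distance: int, angle: int
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one angle."""
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = pixels.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError("co-occurrence offset larger than image")
    # slice out the source/destination regions related by the offset
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = pixels[r0:r1, c0:c1].ravel()
    b = pixels[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    mat = np.zeros((levels, levels), dtype=float)
    np.add.at(mat, (a, b), 1.0)
    mat = mat + mat.T
    total = mat.sum()
    if total == 0:
        raise ValueError("no pixel pairs for the configured offset")
    return mat / total


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_features_single(P: np.ndarray) -> dict:
    """The 13 statistics of one normalized co-occurrence matrix."""
    L = P.shape[0]
    i = np.arange(L, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sd_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sd_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))
    ii, jj = np.meshgrid(i, i, indexing="ij")

    # sum / difference marginal distributions
    p_sum = np.zeros(2 * L - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), P.ravel())
    p_diff = np.zeros(L)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), P.ravel())
    k_sum = np.arange(2 * L - 1, dtype=float)
    k_diff = np.arange(L, dtype=float)

    if sd_x > 0 and sd_y > 0:
        correlation = float((np.sum(ii * jj * P) - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0
    sum_average = float(np.sum(k_sum * p_sum))
    diff_average = float(np.sum(k_diff * p_diff))
    return {
        "Correlation": correlation,
        "Difference of entropy": _entropy(p_diff),
        "Difference of variance": float(np.sum((k_diff - diff_average) ** 2 * p_diff)),
        "Sum of average": sum_average,
        "Sum of entropy": _entropy(p_sum),
        "Sum of squares": float(np.sum((ii - mu_x) ** 2 * P)),
        "Sum of variance": float(np.sum((k_sum - sum_average) ** 2 * p_sum)),
        "Contrast": float(np.sum((ii - jj) ** 2 * P)),
        "Energy": float(np.sum(P * P)),
        "Entropy": _entropy(P.ravel()),
        "Local homogeneity": float(np.sum(P / (1.0 + (ii - jj) ** 2))),
        "Cluster shade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * P)),
        "Cluster prominence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * P)),
    }


def glcm_features(
    pixels: np.ndarray,
    levels: int,
    distance: int = 1,
    angles: Iterable[int] = (0, 45, 90, 135),
) -> dict:
    """The 13 co-occurrence features averaged over the given angles."""
    angles = tuple(angles)
    per_angle = [
        glcm_features_single(cooccurrence_matrix(pixels, levels, distance, a))
        for a in angles
    ]
    return {name: float(np.mean([f[name] for f in per_angle])) for name in NAMES}
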