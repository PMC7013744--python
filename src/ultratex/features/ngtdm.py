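"""Neighbourhood gray-tone difference matrix features.

For every interior pixel the absolute difference between its level and
the mean of its neighbourhood (centre excluded) is accumulated per level:
s(g).  Busyness, coarseness, complexity, contrast and textural strength
follow the classic definitions, with a small epsilon guarding the
denominators that vanish on homogeneous input (a constant block has
coarseness 1/epsilon).
"""

from __future__ import annotations

import numpy as np

NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Textural Strength")


def tone_difference(
    pixels: np.ndarray, levels: int, distance: int = 1
) -> tuple[np.ndarray, np.ndarray, int]:
    """Return (s, n_g, N): per-level difference sums, counts, pixel total."""
    pixels = np.asarray(pixels, dtype=np.int64)
    h, w = pixels.shape
    d = distance
    if h < 2 * d + 1 or w < 2 * d + 1:
        raise ValueError("block too small for the neighbourhood radius")
    center = pixels[d : h - d, d : w - d]
    acc = np.zeros(center.shape, dtype=float)
    for dr in range(-d, d + 1):
        for dc in range(-d, d + 1):
            if dr == 0 and dc == 0:
                continue
            acc += pixels[d + dr : h - d + dr, d + dc : w - d + dc]
    n_neigh = (2 * d + 1) ** 2 - 1
    diff = np.abs(center - acc / n_neigh)
    s = np.zeros(levels, dtype=float)
    n_g = np.zeros(levels, dtype=float)
    np.add.at(s, center.ravel(), diff.ravel())
    np.add.at(n_g, center.ravel(), 1.0)
    return s, n_g, int(center.size)


def ngtdm_features(
    pixels: np.ndarray, levels: int, distance: int = 1, epsilon: float = 1e-6
) -> dict:
    """Five tone-difference statistics over the levels present."""
    s, n_g, N = tone_difference(pixels, levels, distance)
    present = n_g > 0
    p = n_g / N
    g = np.arange(levels, dtype=float)

    gi = g[present]
    pi = p[present]
    si = s[present]
    Ng = int(present.sum())

    coarseness = 1.0 / (epsilon + float(np.sum(pi * si)))

    # pairwise grids over present levels
    GI, GJ = np.meshgrid(gi, gi, indexing="ij")
    PI, PJ = np.meshgrid(pi, pi, indexing="ij")
    SI, SJ = np.meshgrid(si, si, indexing="ij")

    if Ng > 1:
        contrast = (
            float(np.sum(PI * PJ * (GI - GJ) ** 2)) / (Ng * (Ng - 1))
        ) * (float(np.sum(si)) / N)
        busy_den = float(np.sum(np.abs(GI * PI - GJ * PJ)))
        busyness = float(np.sum(pi * si)) / (busy_den + epsilon) if busy_den > 0 else 0.0
        complexity = float(
            np.sum(np.abs(GI - GJ) / (N * (PI + PJ)) * (PI * SI + PJ * SJ))
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
    strength = float(np.sum((PI + PJ) * (GI - GJ) ** 2)) / (epsilon + float(np.sum(si)))
    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Textural Strength": strength,
    }
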