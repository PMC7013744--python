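"""Neighbouring gray-level dependence matrix features.

For each interior pixel of level g, the dependence k is the number of
neighbours within Chebyshev distance d whose level differs by at most the
tolerance a.  Q(g, k) counts those pixels; features are the small/large
number emphases, number non-uniformity, second moment and entropy of the
normalized matrix.  Cells at k = 0 carry no inverse-square mass in the
small-number emphasis.
"""

from __future__ import annotations

import numpy as np

NAMES = (
    "Small number emphasis",
    "Large number emphasis",
    "Number non-uniformity",
    "Second moment",
    "Entropy",
)


def dependence_matrix(
    pixels: np.ndarray, levels: int, distance: int = 1, tolerance: int = 0
) -> np.ndarray:
    """Q(g, k) over interior pixels (no boundary padding)."""
    pixels = np.asarray(pixels)
    h, w = pixels.shape
    d = distance
    if h < 2 * d + 1 or w < 2 * d + 1:
        raise ValueError("block too small for the neighbourhood radius")
    center = pixels[d : h - d, d : w - d]
    k = np.zeros(center.shape, dtype=np.int64)
    for dr in range(-d, d + 1):
        for dc in range(-d, d + 1):
            if dr == 0 and dc == 0:
                continue
            nb = pixels[d + dr : h - d + dr, d + dc : w - d + dc]
            k += np.abs(nb - center) <= tolerance
    n_neigh = (2 * d + 1) ** 2 - 1
    Q = np.zeros((levels, n_neigh + 1), dtype=float)
    np.add.at(Q, (center.ravel(), k.ravel()), 1.0)
    return Q


def ngldm_features(
    pixels: np.ndarray, levels: int, distance: int = 1, tolerance: int = 0
) -> dict:
    """Five dependence-matrix statistics (normalized by the matrix total)."""
    Q = dependence_matrix(pixels, levels, distance, tolerance)
    S = Q.sum()
    k = np.arange(Q.shape[1], dtype=float)
    q_k = Q.sum(axis=0)
    pos = k > 0
    p = Q / S
    p_nz = p[p > 0]
    return {
        "Small number emphasis": float(np.sum(q_k[pos] / k[pos] ** 2) / S),
        "Large number emphasis": float(np.sum(q_k * k**2) / S),
        "Number non-uniformity": float(np.sum(q_k**2) / S),
        "Second moment": float(np.sum(p * p)),
        "Entropy": float(-np.sum(p_nz * np.log2(p_nz))),
    }
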