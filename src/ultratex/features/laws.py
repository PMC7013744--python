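"""Laws texture-energy features.

Five 5x5 masks are built as outer products of the level (L5), edge (E5)
and spot (S5) vectors — LE, EL, SL, EE and LS, where the first letter
gives the row vector.  The block is convolved with each mask (valid
region only) and the mean and variance of the absolute response are the
features.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np
from scipy.signal import convolve2d

MASK_ORDER = ("LE", "EL", "SL", "EE", "LS")
NAMES = tuple(f"{m} mean" for m in MASK_ORDER) + tuple(f"{m} variance" for m in MASK_ORDER)


def laws_masks(
    vectors: Tuple[Tuple[int, ...], Tuple[int, ...], Tuple[int, ...]]
) -> Dict[str, np.ndarray]:
    """The five 5x5 masks keyed by two-letter name (row letter first)."""
    l5, e5, s5 = (np.asarray(v, dtype=float) for v in vectors)
    named = {"L": l5, "E": e5, "S": s5}
    return {
        name: np.outer(named[name[0]], named[name[1]]) for name in MASK_ORDER
    }


def laws_features(
    pixels: np.ndarray,
    vectors: Tuple[Tuple[int, ...], Tuple[int, ...], Tuple[int, ...]],
) -> dict:
    """Mean and variance of |mask response| for the five masks."""
    pixels = np.asarray(pixels, dtype=float)
    if min(pixels.shape) < 5:
        raise ValueError("block smaller than the 5x5 Laws masks")
    means = {}
    variances = {}
    for name, mask in laws_masks(vectors).items():
        resp = np.abs(convolve2d(pixels, mask, mode="valid"))
        means[f"{name} mean"] = float(resp.mean())
        variances[f"{name} variance"] = float(resp.var())
    return {**means, **variances}  # table order: all means, then all variances
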