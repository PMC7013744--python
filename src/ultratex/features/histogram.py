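"""First-order (histogram) statistics of a gray-level block.

Seven features: energy and entropy of the normalized gray-level histogram,
and the mean, variance, standard deviation, skewness and kurtosis of the
pixel distribution.  Entropy is in bits; skewness and kurtosis (excess) are
defined as 0 for a constant block.
"""

from __future__ import annotations

import numpy as np

NAMES = ("Energy", "Entropy", "Kurtosis", "Mean", "Skewness", "Standard Deviation", "Variance")


def histogram_features(pixels: np.ndarray) -> dict:
    """Return the 7 first-order features keyed by name (table order)."""
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty block")
    # histogram over the distinct values actually present
    _, counts = np.unique(x, return_counts=True)
    p = counts / x.size
    energy = float(np.sum(p * p))
    entropy = float(-np.sum(p * np.log2(p)))
    mean = float(x.mean())
    var = float(x.var())  # population moment
    sd = float(np.sqrt(var))
    if sd > 0:
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    return {
        "Energy": energy,
        "Entropy": entropy,
        "Kurtosis": kurt,
        "Mean": mean,
        "Skewness": skew,
        "Standard Deviation": sd,
        "Variance": var,
    }
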