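"""Statistical feature matrix: the dissimilarity measure.

Dissimilarity is the mean absolute gray-level difference between pixel
pairs related by the configured displacement set, averaged over
displacements.
"""

from __future__ import annotations

from typing import Iterable, Tuple

import numpy as np

NAMES = ("Dissimilarity",)


def sfm_dissimilarity(
    pixels: np.ndarray,
    displacements: Iterable[Tuple[int, int]] = ((0, 1), (-1, 1), (-1, 0), (-1, -1)),
) -> dict:
    """Mean absolute pairwise difference per displacement, averaged."""
    pixels = np.asarray(pixels, dtype=float)
    h, w = pixels.shape
    vals = []
    for dr, dc in displacements:
        if abs(dr) >= h or abs(dc) >= w:
            raise ValueError("displacement larger than image")
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = pixels[r0:r1, c0:c1]
        b = pixels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        vals.append(float(np.mean(np.abs(a - b))))
    return {"Dissimilarity": float(np.mean(vals))}
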