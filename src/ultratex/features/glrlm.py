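"""Gray-level run-length matrix features.

A run is a maximal sequence of equal gray levels along a direction.  The
run-length matrix r(g, l) counts runs of level g and length l; the five
classic emphases are computed per direction and averaged over the
configured direction set.
"""

from __future__ import annotations

from typing import Iterable, List

import numpy as np

NAMES = (
    "Short-run emphasis",
    "Long-run emphasis",
    "Gray-level uniformity",
    "Run-length uniformity",
    "Run percentage",
)

#: step (drow, dcol) per scan direction in degrees
DIRECTION_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def _direction_lines(pixels: np.ndarray, angle: int) -> List[np.ndarray]:
    """Pixel sequences along every line of the image in one direction."""
    h, w = pixels.shape
    if angle == 0:
        return [pixels[r, :] for r in range(h)]
    if angle == 90:
        return [pixels[:, c] for c in range(w)]
    if angle == 45:
        # anti-diagonals, traversed with row decreasing / col increasing
        flipped = pixels[::-1, :]
        return [np.diagonal(flipped, offset=k) for k in range(-(h - 1), w)]
    if angle == 135:
        # main diagonals, traversed with row and col both increasing;
        # a run is direction-symmetric so orientation does not matter
        return [np.diagonal(pixels, offset=k) for k in range(-(h - 1), w)]
    raise ValueError(f"unsupported direction {angle}")


def run_length_matrix(pixels: np.ndarray, levels: int, angle: int) -> np.ndarray:
    """r(g, l): count of maximal runs of level g with length l (1-based l)."""
    h, w = pixels.shape
    max_len = max(h, w)
    mat = np.zeros((levels, max_len), dtype=float)
    for line in _direction_lines(pixels, angle):
        line = np.asarray(line)
        if line.size == 0:
            continue
        # boundaries of maximal runs
        change = np.flatnonzero(np.diff(line) != 0)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change, [line.size - 1]))
        for s, e in zip(starts, ends):
            mat[line[s], e - s] += 1.0
    return mat


def glrlm_features_single(mat: np.ndarray, n_pixels: int) -> dict:
    """Five run-length statistics of one direction's matrix."""
    n_runs = mat.sum()
    lengths = np.arange(1, mat.shape[1] + 1, dtype=float)
    run_per_length = mat.sum(axis=0)
    run_per_level = mat.sum(axis=1)
    return {
        "Short-run emphasis": float(np.sum(run_per_length / lengths**2) / n_runs),
        "Long-run emphasis": float(np.sum(run_per_length * lengths**2) / n_runs),
        "Gray-level uniformity": float(np.sum(run_per_level**2) / n_runs),
        "Run-length uniformity": float(np.sum(run_per_length**2) / n_runs),
        "Run percentage": float(n_runs / n_pixels),
    }


def glrlm_features(
    pixels: np.ndarray,
    levels: int,
    directions: Iterable[int] = (0, 45, 90, 135),
) -> dict:
    """Run-length features averaged over the configured directions."""
    pixels = np.asarray(pixels)
    per_dir = [
        glrlm_features_single(run_length_matrix(pixels, levels, a), pixels.size)
        for a in directions
    ]
    return {name: float(np.mean([f[name] for f in per_dir])) for name in NAMES}
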