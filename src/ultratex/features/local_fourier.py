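"""Local Fourier coefficients of the 8-neighbour ring.

For every interior pixel the 8 neighbours are read clockwise starting
east (east, south-east, south, ..., north-east in image coordinates) and
the unnormalized 8-point DFT is taken.  The 32 features are the means and
standard deviations, over interior pixels, of the 8 coefficient
magnitudes and the 8 phase angles.  The phase of a (numerically) zero
coefficient is defined as 0.
"""

from __future__ import annotations

import numpy as np

#: neighbour offsets (drow, dcol), clockwise from east with row axis down
RING_OFFSETS = (
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
)

NAMES = (
    tuple(f"Mean of magnitude {u}" for u in range(8))
    + tuple(f"Mean of phase angle {u}" for u in range(8))
    + tuple(f"SD of magnitude {u}" for u in range(8))
    + tuple(f"SD of phase angle {u}" for u in range(8))
)

_ZERO_TOL = 1e-9


def local_fourier_features(pixels: np.ndarray) -> dict:
    """The 32 ring-DFT statistics keyed by name (table order)."""
    pixels = np.asarray(pixels, dtype=float)
    h, w = pixels.shape
    if h < 3 or w < 3:
        raise ValueError("block must be at least 3x3")
    # stack the 8 neighbour planes of the interior: (n_interior, 8)
    ring = np.stack(
        [pixels[1 + dr : h - 1 + dr, 1 + dc : w - 1 + dc].ravel() for dr, dc in RING_OFFSETS],
        axis=1,
    )
    coeffs = np.fft.fft(ring, axis=1)
    mags = np.abs(coeffs)
    # snap negligible components to zero so the phase of (numerically)
    # real or imaginary coefficients is deterministic on the branch cut
    tol = _ZERO_TOL * (1.0 + mags)
    re = np.where(np.abs(coeffs.real) <= tol, 0.0, coeffs.real)
    im = np.where(np.abs(coeffs.imag) <= tol, 0.0, coeffs.imag)
    phases = np.arctan2(im, re)
    phases[mags <= _ZERO_TOL] = 0.0
    out = {}
    mag_mean, mag_sd = mags.mean(axis=0), mags.std(axis=0)
    ph_mean, ph_sd = phases.mean(axis=0), phases.std(axis=0)
    for u in range(8):
        out[f"Mean of magnitude {u}"] = float(mag_mean[u])
    for u in range(8):
        out[f"Mean of phase angle {u}"] = float(ph_mean[u])
    for u in range(8):
        out[f"SD of magnitude {u}"] = float(mag_sd[u])
    for u in range(8):
        out[f"SD of phase angle {u}"] = float(ph_sd[u])
    return out
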