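"""One-level 2-D discrete wavelet transform: the LL (approximation) subband.

An orthonormal basis (Haar by default) with symmetric half-point boundary
extension; a 23x23 block yields a 12x12 LL subband.  Texture families are
re-applied to this subband after re-quantization; its raw mean and
standard deviation are kept as two extra features.
"""

from __future__ import annotations

import numpy as np
import pywt


def wavelet_ll(pixels: np.ndarray, wavelet: str = "haar", mode: str = "symmetric") -> np.ndarray:
    """LL subband of a one-level 2-D DWT (real-valued)."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or min(pixels.shape) < 2:
        raise ValueError("block must be at least 2x2")
    ll, _ = pywt.dwt2(pixels, wavelet, mode=mode)
    return ll
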