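"""The 126-feature texture bank.

One ROI block yields an ordered vector of 126 real features:

====== ===============================================================
F1-F7    histogram statistics of the raw block
F8-F20   co-occurrence (gray-level spatial dependence) features
F21      statistical-feature-matrix dissimilarity
F22-F26  run-length features
F27-F36  Laws texture-energy features
F37-F41  neighbouring gray-level dependence features
F42-F46  neighbourhood gray-tone difference features
F47-F94  the same families re-applied to the one-level wavelet LL
         subband, plus its raw mean (F73) and standard deviation (F74)
F95-F126 local-Fourier ring statistics
====== ===============================================================

Matrix families operate on a min-max re-quantized copy of the block
(32 levels by default); histogram, Laws and local-Fourier features use
the raw gray levels.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from ..config import MatrixFamilyConfig
from ..image import ROIBlock, quantize
from . import histogram, glcm, sfm, glrlm, laws, ngldm, ngtdm, local_fourier
from .wavelet import wavelet_ll

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_IDS",
    "N_FEATURES",
    "extract_all",
    "extract_named",
    "feature_name",
    "wavelet_ll",
]

#: ordered feature names, F1 first
FEATURE_NAMES = (
    histogram.NAMES
    + glcm.NAMES
    + sfm.NAMES
    + glrlm.NAMES
    + laws.NAMES
    + ngldm.NAMES
    + ngtdm.NAMES
    + tuple(f"Wavelet {n}" for n in histogram.NAMES)
    + tuple(f"Wavelet {n}" for n in glcm.NAMES)
    + tuple(f"Wavelet {n}" for n in sfm.NAMES)
    + tuple(f"Wavelet {n}" for n in glrlm.NAMES)
    + ("Wavelet Mean (raw LL)", "Wavelet Standard deviation (raw LL)")
    + tuple(f"Wavelet {n}" for n in laws.NAMES)
    + tuple(f"Wavelet {n}" for n in ngldm.NAMES)
    + tuple(f"Wavelet {n}" for n in ngtdm.NAMES)
    + local_fourier.NAMES
)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 126

#: feature identifiers "F1".."F126"
FEATURE_IDS = tuple(f"F{i}" for i in range(1, N_FEATURES + 1))


def feature_name(fid: str | int) -> str:
    """Human-readable name for a feature id ("F4" or 4 -> "Mean")."""
    idx = int(str(fid).lstrip("Ff")) - 1
    return FEATURE_NAMES[idx]


def _family_values(
    pixels: np.ndarray, cfg: MatrixFamilyConfig, quantize_all: bool = False
) -> list:
    """Histogram + matrix-family + Laws features of one (sub)image.

    Matrix families always see the re-quantized image; with
    ``quantize_all`` the histogram and Laws families do too (used for the
    real-valued wavelet subband).
    """
    q = quantize(pixels, cfg.quant_levels)
    hist_src = q if quantize_all else pixels
    laws_src = q if quantize_all else pixels
    vals = list(histogram.histogram_features(hist_src).values())
    vals += list(
        glcm.glcm_features(q, cfg.quant_levels, cfg.glcm_distance, cfg.glcm_angles).values()
    )
    vals += list(sfm.sfm_dissimilarity(q, cfg.sfm_displacements).values())
    vals += list(glrlm.glrlm_features(q, cfg.quant_levels, cfg.glrlm_directions).values())
    vals += list(laws.laws_features(laws_src, cfg.laws_vectors).values())
    vals += list(
        ngldm.ngldm_features(q, cfg.quant_levels, cfg.ngldm_distance, cfg.ngldm_tolerance).values()
    )
    vals += list(
        ngtdm.ngtdm_features(q, cfg.quant_levels, cfg.ngtdm_distance, cfg.epsilon).values()
    )
    return vals


def extract_all(block: ROIBlock | np.ndarray, cfg: MatrixFamilyConfig | None = None) -> np.ndarray:
    """Full 126-entry feature vector of one block, in table order.

    The block must be at least 9x9 so the wavelet LL subband admits the
    5x5 Laws masks.  Deterministic for fixed input and configuration.
    """
    cfg = cfg or MatrixFamilyConfig()
    pixels = block.pixels if isinstance(block, ROIBlock) else np.asarray(block)
    if min(pixels.shape) < 9:
        raise ValueError("extract_all needs a block of at least 9x9 pixels")

    # spatial domain: histogram (7), GLCM (13), SFM (1), GLRLM (5),
    # Laws (10), NGLDM (5), NGTDM (5) — F1-F46 in table order
    values: list = _family_values(pixels, cfg)

    # wavelet domain: same families on the LL subband, raw mean/SD inserted
    ll = wavelet_ll(pixels, cfg.wavelet, cfg.wavelet_mode)
    wav = _family_values(ll, cfg, quantize_all=True)
    values += wav[:26]  # F47-F72: histogram .. GLRLM
    values += [float(ll.mean()), float(ll.std())]  # F73, F74
    values += wav[26:46]  # F75-F94: Laws, NGLDM, NGTDM on LL

    # local Fourier ring statistics: F95-F126
    values += list(local_fourier.local_fourier_features(pixels).values())

    out = np.asarray(values, dtype=float)
    if out.shape != (N_FEATURES,) or not np.all(np.isfinite(out)):
        raise RuntimeError("feature extraction produced an invalid vector")
    return out


def extract_named(block: ROIBlock | np.ndarray, cfg: MatrixFamilyConfig | None = None) -> Dict[str, float]:
    """Feature vector keyed by id: {"F1": ..., ..., "F126": ...}."""
    vec = extract_all(block, cfg)
    return dict(zip(FEATURE_IDS, vec.tolist()))
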