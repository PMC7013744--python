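"""Gray-level images, quantization and ROI tiling.

Images are plain 2-D integer numpy arrays (row-major, 0-based).  A region
of interest is given as a same-size binary mask; feature extraction tiles
it into fixed-size square blocks (23x23 by default) and keeps only tiles
that lie fully inside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

DEFAULT_BLOCK_SIZE = 23


@dataclass
class ROIBlock:
    """One grayscale tile cut from a region of interest.

    ``pixels`` holds integer gray levels in ``[0, levels - 1]``;
    ``block_row``/``block_col`` are the 0-based tile indices within the
    source image and ``source_id`` names the sample the tile came from.
    """

    pixels: np.ndarray
    levels: int = 256
    block_row: int = 0
    block_col: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("block pixels must be a non-empty 2-D array")
        if self.pixels.min() < 0 or self.pixels.max() > self.levels - 1:
            raise ValueError("pixel values must lie in [0, levels-1]")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def quantize(pixels: np.ndarray, levels: int) -> np.ndarray:
    """Min–max re-bin an image to ``levels`` gray levels.

    The mapping is monotone linear: bin edges divide ``[min, max]`` evenly
    and the top edge is inclusive.  A constant image maps entirely to
    level 0.  Works for integer and real-valued input (e.g. a wavelet
    subband).
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.size == 0:
        raise ValueError("cannot quantize an empty image")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.int64)
    q = np.floor((pixels - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def tile_blocks(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    block_size: int = DEFAULT_BLOCK_SIZE,
    source_id: str = "",
) -> List[ROIBlock]:
    """Tile an image left-to-right, top-to-bottom into fully-masked blocks.

    Only tiles whose every pixel lies inside the mask (nonzero) are
    returned; partial tiles at the border are dropped.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    mask = np.asarray(mask) != 0
    if mask.shape != image.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    blocks: List[ROIBlock] = []
    n_rows = image.shape[0] // block_size
    n_cols = image.shape[1] // block_size
    for br in range(n_rows):
        for bc in range(n_cols):
            sl = (
                slice(br * block_size, (br + 1) * block_size),
                slice(bc * block_size, (bc + 1) * block_size),
            )
            if mask[sl].all():
                blocks.append(
                    ROIBlock(
                        pixels=image[sl].astype(np.int64),
                        levels=256,
                        block_row=br,
                        block_col=bc,
                        source_id=source_id,
                    )
                )
    return blocks
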