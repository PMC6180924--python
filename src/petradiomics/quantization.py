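"""Grey-level quantization of a VOI.

SUVs inside the mask are digitized into ``B`` equal-width bins spanning the
min-max range of the segmented volume (default 64 bins).  All texture
matrices operate on these integer levels, which makes them invariant under
any positive affine rescaling of the raw uptake values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume, VOIMask

__all__ = ["QuantizedVOI", "quantize"]


@dataclass
class QuantizedVOI:
    """Integer grey levels over a mask.

    ``levels`` is a 3D int array: values in ``1..n_bins`` inside the mask and
    0 outside (0 is never a valid level, so the array doubles as the mask).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    vmin: float
    vmax: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_levels(self) -> np.ndarray:
        """1D array of levels for the mask voxels (array order)."""
        return self.levels[self.mask]


def quantize(vol: ImageVolume, mask: VOIMask, n_bins: int = 64) -> QuantizedVOI:
    """Min-max bin the VOI: ``level = min(B, floor((v - vmin)/(vmax - vmin) * B) + 1)``.

    A degenerate VOI (all voxels equal) maps entirely to level 1.

    Raises
    ------
    ValueError
        If ``n_bins < 2`` or the mask is empty.
    """
    if n_bins < 2:
        raise ValueError(f"need at least 2 bins, got {n_bins}")
    m = mask.mask
    if not m.any():
        raise ValueError("cannot quantize an empty mask")
    values = vol.data[m]
    vmin, vmax = float(values.min()), float(values.max())
    levels = np.zeros(vol.data.shape, dtype=np.int64)
    if vmax > vmin:
        lv = np.floor((values - vmin) / (vmax - vmin) * n_bins).astype(np.int64) + 1
        np.minimum(lv, n_bins, out=lv)
        levels[m] = lv
    else:
        levels[m] = 1
    return QuantizedVOI(levels=levels, mask=m.copy(), n_bins=n_bins, vmin=vmin, vmax=vmax)
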