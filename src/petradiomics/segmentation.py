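"""Semiautomatic tumor delineation.

The lesion is delineated as the set of voxels at or above a fixed fraction
(default 40%) of the global maximum uptake, restricted to the 26-connected
component containing the hottest voxel.  Because the threshold is relative,
the segmentation is invariant under any positive rescaling of the image.

Lesions whose physical volume falls below 2.6 ml are excluded from feature
analysis: run-length and zone statistics become unstable when only a handful
of voxels is available.  2.6 ml is the volume of the third-smallest sphere
(17 mm inner diameter) of the NEMA IEC image-quality phantom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume, VOIMask

__all__ = [
    "segment_isocontour",
    "compute_volume_ml",
    "apply_volume_filter",
    "VolumeFilterResult",
    "VOLUME_THRESHOLD_ML",
]

logger = logging.getLogger(__name__)

#: Minimal physical tumor volume (ml) at which texture features are trusted.
VOLUME_THRESHOLD_ML = 2.6

# full 3x3x3 neighbourhood => 26-connectivity
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def segment_isocontour(vol: ImageVolume, fraction: float = 0.40) -> VOIMask:
    """Threshold at ``fraction * max(SUV)`` and keep the component of the peak.

    The mask is the 26-connected component of ``{v : SUV(v) >= fraction * SUVmax}``
    that contains the global-maximum voxel.  Ties for the maximum are anchored
    at the first tied voxel in array order; every tied voxel is above threshold
    and connected components are unaffected by the anchor choice within a
    component.

    Raises
    ------
    ValueError
        If the volume is identically zero (no maximum uptake to key on) or the
        fraction is outside (0, 1).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"isocontour fraction must lie in (0, 1), got {fraction}")
    data = vol.data
    vmax = float(data.max())
    if vmax <= 0.0:
        raise ValueError("cannot segment an all-zero volume: no maximum uptake")
    threshold = fraction * vmax
    above = data >= threshold
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    anchor = np.unravel_index(int(np.argmax(data)), data.shape)
    mask = labels == labels[anchor]
    return VOIMask(mask=mask, spacing_mm=vol.spacing_mm, origin_mm=vol.origin_mm)


def compute_volume_ml(mask: VOIMask | np.ndarray,
                      spacing_mm: tuple[float, float, float] | None = None) -> float:
    """Physical mask volume in ml: ``voxel_count * dx*dy*dz / 1000``."""
    if isinstance(mask, VOIMask):
        m, spacing = mask.mask, mask.spacing_mm
    else:
        if spacing_mm is None:
            raise ValueError("spacing_mm required when mask is a bare array")
        m, spacing = np.asarray(mask, dtype=bool), spacing_mm
    count = int(m.sum())
    if count == 0:
        warnings.warn("empty mask: volume is 0.0 ml", stacklevel=2)
        return 0.0
    return count * float(np.prod(spacing)) / 1000.0


@dataclass
class VolumeFilterResult:
    """Outcome of the small-tumor exclusion rule."""

    retained: list[int]
    excluded: list[int]
    volumes_ml: list[float]
    threshold_ml: float

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def apply_volume_filter(masks: list[VOIMask],
                        threshold_ml: float = VOLUME_THRESHOLD_ML) -> VolumeFilterResult:
    """Partition subjects by the small-volume rule (excluded iff volume < threshold).

    The comparison is strict: a tumor of exactly ``threshold_ml`` is retained.
    Each exclusion is logged with its measured volume.
    """
    volumes = [m.volume_ml for m in masks]
    retained, excluded = [], []
    for i, v in enumerate(volumes):
        if v < threshold_ml:
            excluded.append(i)
            logger.info("subject %d excluded: volume %.3f ml < %.1f ml", i, v, threshold_ml)
        else:
            retained.append(i)
    return VolumeFilterResult(retained=retained, excluded=excluded,
                              volumes_ml=volumes, threshold_ml=threshold_ml)
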