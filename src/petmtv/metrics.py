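"""Scalar quantification of masks over SUV volumes.

MTV (metabolic tumor volume) is the volume in ml of the segmented voxels.
TLG (total lesion glycolysis) is SUVmean over the segmented voxels times
MTV — equivalently the per-voxel SUV sum times the voxel volume.  SUVmean
is the unweighted arithmetic mean over included voxels (no partial-volume
weighting), matching threshold-mask semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image import SuvVolume, VoiMask

__all__ = ["LesionMetrics", "mtv_ml", "tlg", "suv_mean", "suv_max", "lesion_metrics"]


@dataclass(frozen=True)
class LesionMetrics:
    """SUV statistics and volume totals for one volume of interest."""

    suv_max: float
    suv_peak: float
    suv_mean: float
    mtv_ml: float
    tlg: float


def mtv_ml(mask: VoiMask) -> float:
    """Metabolic tumor volume in ml: voxel count times voxel volume."""
    return mask.volume_ml


def suv_mean(volume: SuvVolume, mask: VoiMask) -> float:
    mask.check_aligned(volume)
    if mask.voxel_count == 0:
        raise ValueError("SUVmean undefined for an empty mask")
    return float(volume.values[mask.values].mean(dtype=np.float64))


def suv_max(volume: SuvVolume, mask: VoiMask) -> float:
    mask.check_aligned(volume)
    if mask.voxel_count == 0:
        raise ValueError("SUVmax undefined for an empty mask")
    return float(volume.values[mask.values].max())


def tlg(volume: SuvVolume, mask: VoiMask) -> float:
    """Total lesion glycolysis: SUVmean in the mask times its MTV (SUV·ml).

    An empty mask yields 0 with a warning (no lesion, no glycolysis).
    """
    mask.check_aligned(volume)
    if mask.voxel_count == 0:
        warnings.warn("TLG of an empty mask is 0", stacklevel=2)
        return 0.0
    return float(
        volume.values[mask.values].sum(dtype=np.float64) * mask.voxel_volume_ml
    )


def lesion_metrics(volume: SuvVolume, mask: VoiMask) -> LesionMetrics:
    """All scalar metrics for one mask (SUVpeak per the 1 ml sphere rule)."""
    from .segmentation import suv_peak  # local import avoids a cycle

    return LesionMetrics(
        suv_max=suv_max(volume, mask),
        suv_peak=suv_peak(volume, mask),
        suv_mean=suv_mean(volume, mask),
        mtv_ml=mtv_ml(mask),
        tlg=tlg(volume, mask),
    )
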