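"""Lung-masked quantitative densitometry.

The four standard emphysema markers — %LAA-950, mean lung attenuation,
Perc15 and total lung volume — plus a per-axial-slice LAA curve, always
computed from un-windowed HU values. The canonical analysis grid is
1 mm isotropic: :func:`compute_markers` resamples first if needed.

Conventions (fixed because they differ between tools):

* LAA counts voxels strictly *below* the threshold (default -950 HU);
  a voxel at exactly -950 HU is not low-attenuation.
* Percentiles use linear interpolation between closest order statistics
  (position ``1 + q*(n-1)`` on the sorted sample).
* Axial slices with no lung voxels get a missing (NaN) curve entry, not
  a zero, so plots show gaps rather than fake values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import EmptyMaskError
from .segment import LungMask, resample_isotropic
from .volume import CTVolume

LAA_THRESHOLD_HU = -950.0


@dataclass
class QCTMarkers:
    """Per-scan densitometry bundle."""

    laa950_pct: float
    mean_hu: float
    perc15_hu: Optional[float] = None
    tlv_l: Optional[float] = None
    laa_curve: Optional[np.ndarray] = None
    laa_threshold_hu: float = LAA_THRESHOLD_HU
    patient_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.laa950_pct <= 100.0:
            raise ValueError("laa950_pct must lie in [0, 100]")
        if self.tlv_l is not None and self.tlv_l <= 0:
            raise ValueError("tlv_l must be positive")
        if self.laa_curve is not None:
            curve = np.asarray(self.laa_curve, dtype=float)
            defined = curve[~np.isnan(curve)]
            if defined.size and (defined.min() < 0 or defined.max() > 100):
                raise ValueError("laa_curve entries must lie in [0, 100]")
            self.laa_curve = curve

    def to_row(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "laa950_pct": self.laa950_pct,
            "mean_hu": self.mean_hu,
            "perc15_hu": self.perc15_hu,
            "tlv_l": self.tlv_l,
        }


def _masked_values(volume: CTVolume, mask: LungMask) -> np.ndarray:
    if mask.shape != volume.shape:
        raise ValueError("mask and volume grids differ")
    vals = volume.voxels[mask.voxels.astype(bool)]
    if vals.size == 0:
        raise EmptyMaskError("empty mask")
    return vals


def laa_percent(
    volume: CTVolume, mask: LungMask, threshold: float = LAA_THRESHOLD_HU
) -> float:
    """Percentage of lung voxels with attenuation strictly below threshold."""
    vals = _masked_values(volume, mask)
    return 100.0 * float(np.count_nonzero(vals < threshold)) / vals.size


def mean_lung_hu(volume: CTVolume, mask: LungMask) -> float:
    """Arithmetic mean attenuation over the lung mask, HU."""
    return float(_masked_values(volume, mask).mean())


def perc15(volume: CTVolume, mask: LungMask) -> float:
    """15th percentile of the lung HU distribution (linear interpolation)."""
    return float(np.percentile(_masked_values(volume, mask), 15))


def total_lung_volume(mask: LungMask) -> float:
    """Lung volume in litres: voxel count times voxel volume."""
    return mask.volume_l()


def laa_slice_curve(
    volume: CTVolume, mask: LungMask, threshold: float = LAA_THRESHOLD_HU
) -> np.ndarray:
    """Per-axial-slice LAA percentage; NaN where a slice has no lung.

    The mask-voxel-weighted mean of the defined entries equals the global
    LAA percentage (an algebraic identity, preserved exactly).
    """
    if mask.shape != volume.shape:
        raise ValueError("mask and volume grids differ")
    m = mask.voxels.astype(bool)
    below = (volume.voxels < threshold) & m
    per_slice_n = m.sum(axis=(1, 2)).astype(float)
    per_slice_b = below.sum(axis=(1, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(per_slice_n > 0, 100.0 * per_slice_b / per_slice_n, np.nan)
    return curve


def compute_markers(
    volume: CTVolume,
    mask: LungMask,
    threshold: float = LAA_THRESHOLD_HU,
    resample: bool = True,
) -> QCTMarkers:
    """Compute the full marker bundle on the 1 mm isotropic grid.

    If the inputs are not already isotropic 1 mm and ``resample`` is true,
    both are resampled (image trilinear, mask nearest-neighbour) first.
    """
    if resample:
        volume = resample_isotropic(volume, 1.0)
        mask = resample_isotropic(mask, 1.0)
    return QCTMarkers(
        laa950_pct=laa_percent(volume, mask, threshold),
        mean_hu=mean_lung_hu(volume, mask),
        perc15_hu=perc15(volume, mask),
        tlv_l=total_lung_volume(mask),
        laa_curve=laa_slice_curve(volume, mask, threshold),
        laa_threshold_hu=threshold,
        patient_id=volume.patient_id,
    )
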