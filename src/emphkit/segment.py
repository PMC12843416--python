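"""Isotropic resampling, lung segmentation and plausibility QC.

The canonical analysis grid is 1x1x1 mm; volumes are resampled first and
segmented second. Segmentation is pluggable: the ``fallback`` backend is a
classical threshold-plus-morphology pipeline that needs no trained model,
while the ``external`` backend accepts a mask produced elsewhere (e.g. a
U-Net tool) as a NIfTI file or array and adapts it to the volume grid.

QC never drops scans: it measures lung volume, mean lung attenuation and
axial extent against wide radiological-plausibility bounds and reports
pass/fail per check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .errors import SegmentationError
from .volume import CTVolume

AIR_THRESHOLD_HU = -320.0
"""Upper HU bound for air-like voxels in the fallback segmenter."""

QC_LUNG_VOLUME_L = (0.5, 12.0)
QC_MEAN_LUNG_HU = (-1000.0, -500.0)
QC_MIN_AXIAL_SLICES = 10


@dataclass
class LungMask:
    """Binary lung mask aligned to a :class:`CTVolume` grid."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        vals = np.unique(self.voxels)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be in {0, 1}")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def volume_l(self) -> float:
        dz, dy, dx = self.spacing_mm
        return float(self.voxels.sum()) * dz * dy * dx / 1e6


@dataclass
class QCReport:
    """Plausibility-check outcomes for one volume/mask pair.

    ``passed`` is the conjunction of all individual checks; failures are
    reported, never raised, mirroring a flag-don't-drop QC policy.
    """

    passed: bool
    checks: list[tuple[str, bool, float]] = field(default_factory=list)
    lung_volume_l: float = float("nan")
    mean_lung_hu: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "checks": [
                {"name": n, "passed": p, "value": v} for n, p, v in self.checks
            ],
            "lung_volume_l": self.lung_volume_l,
            "mean_lung_hu": self.mean_lung_hu,
        }


def _target_shape(shape, spacing, target_mm: float) -> tuple[int, ...]:
    return tuple(
        max(1, int(round(n * s / target_mm))) for n, s in zip(shape, spacing)
    )


def resample_isotropic(obj: CTVolume | LungMask, target_mm: float = 1.0):
    """Resample a volume or mask to an isotropic grid.

    Images use trilinear interpolation; masks use nearest-neighbour so the
    output stays binary. Output axis lengths are
    ``round(input_len * input_spacing / target)``, at least 1. A grid that
    is already at the target spacing is returned as a copy unchanged.
    """
    if target_mm <= 0:
        raise ValueError("invalid target spacing: must be > 0")
    is_mask = isinstance(obj, LungMask)
    spacing = obj.spacing_mm
    iso = (target_mm,) * 3
    if np.allclose(spacing, iso, rtol=0, atol=1e-9):
        if is_mask:
            return LungMask(obj.voxels.copy(), iso)
        return CTVolume(obj.voxels.copy(), iso, obj.patient_id, obj.source)

    out_shape = _target_shape(obj.voxels.shape, spacing, target_mm)
    zoom = [o / i for o, i in zip(out_shape, obj.voxels.shape)]
    if is_mask:
        res = ndimage.zoom(obj.voxels, zoom, order=0, mode="nearest")
        res = res[: out_shape[0], : out_shape[1], : out_shape[2]]
        return LungMask(res, iso)
    res = ndimage.zoom(
        obj.voxels.astype(np.float32), zoom, order=1, mode="nearest",
        prefilter=False,
    )
    res = res[: out_shape[0], : out_shape[1], : out_shape[2]]
    return CTVolume(res, iso, obj.patient_id, obj.source)


def _drop_border_components(air: np.ndarray) -> np.ndarray:
    """Remove air components touching the in-plane (y/x) borders.

    Air outside the body reaches the image edge on some slice; lungs do
    not. The z faces are deliberately kept: the trachea may exit the scan
    range axially.
    """
    labels, _ = ndimage.label(air)
    edge = np.unique(
        np.concatenate(
            [
                labels[:, 0, :].ravel(),
                labels[:, -1, :].ravel(),
                labels[:, :, 0].ravel(),
                labels[:, :, -1].ravel(),
            ]
        )
    )
    edge = edge[edge != 0]
    keep = air & ~np.isin(labels, edge)
    return keep


def segment_lungs(
    volume: CTVolume,
    backend: str = "fallback",
    mask_path: str | Path | np.ndarray | None = None,
) -> LungMask:
    """Produce a lung mask for a HU volume.

    fallback backend
        (1) threshold HU < -320 as air candidates, (2) drop components
        touching the in-plane borders (outside-body air), (3) keep the two
        largest 3-D components (one if the runner-up is under 10% of the
        largest), (4) morphological closing (ball radius 2) and per-slice
        hole filling. Deterministic.
    external backend
        Load a mask (NIfTI path or array), binarize nonzero, resample in
        mask mode if its spacing differs from the volume's.
    """
    if backend == "fallback":
        air = volume.voxels < AIR_THRESHOLD_HU
        inside = _drop_border_components(air)
        labels, n = ndimage.label(inside)
        if n == 0:
            raise SegmentationError("segmentation failure: no lung candidate")
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        order = np.argsort(sizes)[::-1]
        keep_ids = [order[0] + 1]
        if n > 1 and sizes[order[1]] >= 0.10 * sizes[order[0]]:
            keep_ids.append(order[1] + 1)
        mask = np.isin(labels, keep_ids)
        mask = ndimage.binary_closing(mask, structure=ball(2))
        for z in range(mask.shape[0]):
            mask[z] = ndimage.binary_fill_holes(mask[z])
        if not mask.any():
            raise SegmentationError("segmentation failure: empty mask")
        return LungMask(mask.astype(np.uint8), volume.spacing_mm)

    if backend == "external":
        if mask_path is None:
            raise SegmentationError("external backend requires mask_path")
        if isinstance(mask_path, np.ndarray):
            data, spacing = mask_path, volume.spacing_mm
        else:
            import nibabel as nib

            img = nib.load(str(mask_path))
            # NIfTI stores (x, y, z); analysis order is (z, y, x)
            data = np.asanyarray(img.dataobj).T
            zooms = img.header.get_zooms()[:3]
            spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        binary = (np.asarray(data) > 0).astype(np.uint8)
        mask = LungMask(binary, spacing)
        spacing_differs = not np.allclose(
            spacing, volume.spacing_mm, rtol=0, atol=1e-6
        )
        if spacing_differs or mask.shape != volume.shape:
            mask = _regrid_mask(mask, volume)
        if not mask.voxels.any():
            raise SegmentationError("segmentation failure: empty external mask")
        return LungMask(mask.voxels, volume.spacing_mm)

    raise SegmentationError(f"unknown segmentation backend: {backend}")


def _regrid_mask(mask: LungMask, volume: CTVolume) -> LungMask:
    """Nearest-neighbour regrid of a mask onto an arbitrary volume grid."""
    zoom = [t / s for t, s in zip(volume.shape, mask.shape)]
    res = ndimage.zoom(mask.voxels, zoom, order=0, mode="nearest")
    res = res[: volume.shape[0], : volume.shape[1], : volume.shape[2]]
    if res.shape != volume.shape:
        raise SegmentationError("mask mismatch: irreconcilable grids")
    return LungMask(res, volume.spacing_mm)


def qc_check(volume: CTVolume, mask: LungMask) -> QCReport:
    """Automated plausibility checks on a segmented scan.

    Checks: non-empty mask; total lung volume within 0.5-12 L; mean lung
    attenuation within [-1000, -500] HU; mask spanning at least 10 axial
    slices. Bounds are deliberately wide — QC flags implausible scans,
    it does not grade segmentation quality.
    """
    if mask.shape != volume.shape:
        raise SegmentationError("mask mismatch: QC needs aligned grids")
    n_vox = int(mask.voxels.sum())
    non_empty = n_vox > 0
    vol_l = mask.volume_l()
    mean_hu = (
        float(volume.voxels[mask.voxels.astype(bool)].mean()) if non_empty
        else float("nan")
    )
    z_extent = int((mask.voxels.any(axis=(1, 2))).sum())

    checks = [
        ("non_empty", non_empty, float(n_vox)),
        ("plausible_volume", QC_LUNG_VOLUME_L[0] <= vol_l <= QC_LUNG_VOLUME_L[1], vol_l),
        (
            "plausible_density",
            non_empty and QC_MEAN_LUNG_HU[0] <= mean_hu <= QC_MEAN_LUNG_HU[1],
            mean_hu,
        ),
        ("axial_extent", z_extent >= QC_MIN_AXIAL_SLICES, float(z_extent)),
    ]
    return QCReport(
        passed=all(p for _, p, _ in checks),
        checks=checks,
        lung_volume_l=vol_l,
        mean_lung_hu=mean_hu,
    )


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
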