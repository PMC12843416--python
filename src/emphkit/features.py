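"""Mid-lung patch sampling and scan-level embedding extraction.

The scan representation is built from 2-D axial patches taken in the
mid-lung band (the central third of the mask's axial extent), where
parenchyma dominates over apical/basal partial-volume slices. Each patch
is centred on its slice's lung centroid, padded with -1000 HU, and
non-lung pixels are replaced by -1000 HU so the backbone sees lung
texture only.

Two embedding backends share one interface:

``texture`` (default)
    A deterministic hand-crafted descriptor per patch — 32-bin intensity
    histogram on the unit-windowed patch, 16-bin gradient-magnitude
    histogram, and 16 summary statistics (moments, quantiles,
    below-threshold fractions) — 64 dimensions, no trained weights, no
    download. Every downstream stage is testable offline with it.

``resnet152-gap``
    Frozen ImageNet ResNet-152, output of the global-average-pooling
    layer, 2048 dimensions. Requires torch/torchvision and locally
    present weights; never downloads.

Patch embeddings are aggregated to a scan vector by the column-wise mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BackendError, EmphkitError
from .segment import LungMask
from .volume import CTVolume, clip_normalize

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

TEXTURE_DIM = 64
_INTENSITY_BINS = 32
_GRADIENT_BINS = 16


@dataclass
class PatchSet:
    """Equal-size 2-D HU patches with their axial slice indices."""

    patches: list[np.ndarray]
    slice_indices: list[int]
    patch_size_px: int
    patient_id: str = ""

    def __post_init__(self) -> None:
        for p in self.patches:
            if p.shape != (self.patch_size_px, self.patch_size_px):
                raise ValueError("all patches must be square of patch_size_px")


@dataclass
class EmbeddingRecord:
    """Per-patch embedding matrix plus its mean-aggregated scan vector."""

    per_patch: np.ndarray
    scan_vector: np.ndarray
    dim: int
    backend_id: str
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.per_patch.shape[1] != self.dim:
            raise ValueError("per_patch width must equal dim")
        if not np.allclose(
            self.scan_vector, self.per_patch.mean(axis=0), atol=1e-9
        ):
            raise ValueError("scan_vector must be the column-wise patch mean")


def mid_lung_band(mask: LungMask) -> tuple[int, int]:
    """Inclusive axial index range of the central third of the lung extent."""
    has_lung = np.flatnonzero(mask.voxels.any(axis=(1, 2)))
    if has_lung.size < 3:
        raise EmphkitError("insufficient lung extent")
    z0, z1 = int(has_lung[0]), int(has_lung[-1])
    nz = z1 - z0 + 1
    lo = z0 + nz // 3
    hi = z0 + (2 * nz) // 3
    return lo, max(lo, hi)


def sample_mid_lung_patches(
    volume: CTVolume,
    mask: LungMask,
    n_patches: int = 9,
    patch_size_px: int = 224,
) -> PatchSet:
    """Sample axial patches evenly across the mid-lung band.

    Slices are chosen evenly spaced over the band (the band's central
    slice when ``n_patches`` is 1); each patch is centred on that slice's
    lung-mask centroid, cropped/padded to the requested size, and
    non-lung pixels are set to -1000 HU.
    """
    if n_patches < 1:
        raise ValueError("invalid count: n_patches must be >= 1")
    if mask.shape != volume.shape:
        raise ValueError("mask and volume grids differ")
    lo, hi = mid_lung_band(mask)
    if n_patches == 1:
        zs = [int(round((lo + hi) / 2))]
    else:
        zs = [int(round(z)) for z in np.linspace(lo, hi, n_patches)]

    half = patch_size_px // 2
    patches = []
    for z in zs:
        sl_mask = mask.voxels[z].astype(bool)
        if sl_mask.any():
            cy, cx = (int(round(c)) for c in np.argwhere(sl_mask).mean(axis=0))
        else:  # band slice with no lung: fall back to the grid centre
            cy, cx = volume.shape[1] // 2, volume.shape[2] // 2
        patch = np.full((patch_size_px, patch_size_px), -1000.0, dtype=np.float32)
        y0, x0 = cy - half, cx - half
        ys = slice(max(0, y0), min(volume.shape[1], y0 + patch_size_px))
        xs = slice(max(0, x0), min(volume.shape[2], x0 + patch_size_px))
        py = slice(ys.start - y0, ys.stop - y0)
        px = slice(xs.start - x0, xs.stop - x0)
        src = np.where(sl_mask[ys, xs], volume.voxels[z, ys, xs], -1000.0)
        patch[py, px] = src
        patches.append(patch)
    return PatchSet(patches, zs, patch_size_px, patient_id=volume.patient_id)


def normalize_patch(
    patch: np.ndarray,
    mean: tuple[float, float, float] = IMAGENET_MEAN,
    std: tuple[float, float, float] = IMAGENET_STD,
) -> np.ndarray:
    """HU patch -> backbone-ready (3, H, W) float grid.

    Windows to [-1000, 400], rescales to [0, 1], replicates to three
    channels and applies the per-channel affine standardization the
    frozen backbone was trained with.
    """
    unit = clip_normalize(np.asarray(patch, dtype=np.float64))
    out = np.stack([unit, unit, unit], axis=0)
    m = np.asarray(mean, dtype=np.float64)[:, None, None]
    s = np.asarray(std, dtype=np.float64)[:, None, None]
    return (out - m) / s


def _texture_descriptor(patch_hu: np.ndarray) -> np.ndarray:
    """64-d deterministic texture descriptor of one HU patch."""
    unit = clip_normalize(np.asarray(patch_hu, dtype=np.float64))
    hist, _ = np.histogram(unit, bins=_INTENSITY_BINS, range=(0.0, 1.0))
    hist = hist / unit.size

    gy, gx = np.gradient(unit)
    gmag = np.hypot(gy, gx)
    ghist, _ = np.histogram(
        np.clip(gmag, 0.0, 0.5), bins=_GRADIENT_BINS, range=(0.0, 0.5)
    )
    ghist = ghist / gmag.size

    hu = np.asarray(patch_hu, dtype=np.float64)
    centered = unit - unit.mean()
    sd = unit.std()
    skew = float((centered**3).mean() / sd**3) if sd > 0 else 0.0
    kurt = float((centered**4).mean() / sd**4) if sd > 0 else 0.0
    stats = np.array(
        [
            unit.mean(),
            sd,
            unit.min(),
            unit.max(),
            *np.percentile(unit, (5, 15, 25, 50, 75, 95)),
            skew,
            kurt,
            float(np.mean(hu < -950.0)),   # emphysema-range fraction
            float(np.mean(hu < -910.0)),
            float(np.mean(hu < -856.0)),
            float(np.mean(hu > -1000.0 + 1e-6)),  # non-background fraction
        ]
    )
    return np.concatenate([hist, ghist, stats])


def extract_embeddings(
    patchset: PatchSet,
    backend: str = "texture",
    weights_path: str | None = None,
) -> EmbeddingRecord:
    """Embed every patch and aggregate to a scan vector.

    The ``texture`` backend is fully deterministic and has no external
    state. The ``resnet152-gap`` backend refuses to run without torch
    and a locally present weights file — it never downloads.
    """
    if not patchset.patches:
        raise EmphkitError("no patches")
    if backend == "texture":
        per_patch = np.stack(
            [_texture_descriptor(p) for p in patchset.patches]
        )
        dim = TEXTURE_DIM
    elif backend == "resnet152-gap":
        per_patch = _resnet152_gap(patchset, weights_path)
        dim = 2048
    else:
        raise BackendError(f"backend unavailable: {backend!r}")
    return EmbeddingRecord(
        per_patch=per_patch,
        scan_vector=aggregate_scan(per_patch),
        dim=dim,
        backend_id="resnet152-gap" if backend == "resnet152-gap" else "texture",
        patient_id=patchset.patient_id,
    )


def _resnet152_gap(patchset: PatchSet, weights_path: str | None) -> np.ndarray:
    try:
        import torch
        from torchvision.models import resnet152
    except ImportError as exc:  # pragma: no cover - optional backend
        raise BackendError("backend unavailable: torch/torchvision not installed") from exc
    if weights_path is None:  # pragma: no cover - optional backend
        raise BackendError("weights missing: pass a local resnet152 state dict")
    model = resnet152()  # pragma: no cover - optional backend
    state = torch.load(weights_path, map_location="cpu")  # pragma: no cover
    model.load_state_dict(state)  # pragma: no cover
    model.fc = torch.nn.Identity()  # pragma: no cover
    model.eval()  # pragma: no cover
    with torch.no_grad():  # pragma: no cover
        batch = torch.stack(
            [
                torch.from_numpy(normalize_patch(p)).float()
                for p in patchset.patches
            ]
        )
        return model(batch).numpy()


def aggregate_scan(per_patch: np.ndarray) -> np.ndarray:
    """Column-wise mean of patch embeddings (order-invariant)."""
    per_patch = np.asarray(per_patch)
    if per_patch.size == 0 or per_patch.shape[0] == 0:
        raise EmphkitError("no patches")
    return per_patch.mean(axis=0)
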