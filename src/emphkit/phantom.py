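"""Seeded synthetic lung phantoms with known densitometry ground truth.

Each phantom is a chest-like HU volume: air background at -1000 HU, a
soft-tissue body ellipsoid at about +40 HU, and two lung ellipsoids
filled with Gaussian parenchyma. Emphysema is planted as spherical
low-attenuation blobs (about -980 HU) dropped uniformly inside the lungs
until the fraction of lung voxels below -950 HU reaches a requested
target, counted on the final noisy voxel values so the planted %LAA-950
is what densitometry will actually measure on the native grid.

A cohort generator draws class-conditional parameters so that positives
satisfy the dual labeling criteria with margin (>= 1 LAA point and
>= 10 HU from each threshold) and negatives violate at least one with
margin — construction-time truth labels are therefore sharp, not
borderline.

Everything is reproducible from integer seeds; no voxel is random twice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import PhantomError
from .segment import LungMask
from .volume import CTVolume

HU_CLAMP = (-1024.0, 400.0)

_GRID = (84, 144, 144)           # (nz, ny, nx) voxels
_SPACING = (2.0, 1.0, 1.0)       # mm; typical LDCT anisotropy
_LUNG_SEMI_MM = (58.0, 46.0, 28.0)   # per-lung ellipsoid semi-axes (z, y, x)
_LUNG_OFFSET_X_MM = 32.0             # lung centres at body midline +/- offset
_BODY_SEMI_MM = (78.0, 68.0, 70.0)
_SHELL_MM = 5.0   # minimum soft-tissue thickness between lung and outside air


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom.

    HU levels follow chest CT physics: air -1000, soft tissue ~ +40,
    aerated parenchyma in the -900..-750 band, emphysematous lung near
    -980. ``target_laa_pct`` is the planted fraction of lung voxels below
    -950 HU on the final volume; it must stay <= 60 so blobs fit inside
    the lungs.
    """

    grid_shape: tuple[int, int, int] = _GRID
    spacing_mm: tuple[float, float, float] = _SPACING
    body_hu: float = 40.0
    parenchyma_mean_hu: float = -820.0
    parenchyma_sd_hu: float = 25.0
    emphysema_hu_mean: float = -980.0
    emphysema_hu_sd: float = 10.0
    target_laa_pct: float = 0.0
    blob_radius_mm: float = 12.0
    noise_sd_hu: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.emphysema_hu_mean < -950.0 < self.parenchyma_mean_hu):
            raise ValueError(
                "need emphysema_hu_mean < -950 < parenchyma_mean_hu"
            )
        if not 0.0 <= self.target_laa_pct <= 60.0:
            raise ValueError("target_laa_pct must lie in [0, 60]")
        if self.blob_radius_mm <= 0:
            raise ValueError("blob_radius_mm must be positive")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")


@dataclass
class PhantomTruth:
    """A generated phantom with its construction-time ground truth."""

    volume: CTVolume
    lung_mask: LungMask
    true_laa_pct: float
    true_mean_hu: float
    true_label: int
    spec: PhantomSpec


def _ellipsoid(coords_mm, center_mm, semi_mm) -> np.ndarray:
    zz, yy, xx = coords_mm
    cz, cy, cx = center_mm
    az, ay, ax = semi_mm
    return (
        ((zz - cz) / az) ** 2
        + ((yy - cy) / ay) ** 2
        + ((xx - cx) / ax) ** 2
    ) <= 1.0


def analytic_lung_volume_l(spec: PhantomSpec) -> float:
    """Closed-form volume of the two lung ellipsoids, litres."""
    az, ay, ax = _LUNG_SEMI_MM
    return 2.0 * (4.0 / 3.0) * np.pi * az * ay * ax / 1e6


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build one phantom volume, mask and truth record from its spec.

    Blob placement counts below-threshold lung voxels on the final voxel
    values (tissue draw plus the additive noise field) and stops as soon
    as the target count is reached, so the planted %LAA-950 overshoots by
    at most one blob's footprint. Raises when the target cannot be
    reached within a bounded number of placements.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape
    dz, dy, dx = spec.spacing_mm

    z = (np.arange(nz) * dz)[:, None, None]
    y = (np.arange(ny) * dy)[None, :, None]
    x = (np.arange(nx) * dx)[None, None, :]
    center = ((nz - 1) * dz / 2.0, (ny - 1) * dy / 2.0, (nx - 1) * dx / 2.0)

    body = _ellipsoid((z, y, x), center, _BODY_SEMI_MM)
    # lungs are clipped to an eroded body so a soft-tissue shell of at
    # least _SHELL_MM always separates lung air from outside air
    inner = _ellipsoid(
        (z, y, x), center, tuple(s - _SHELL_MM for s in _BODY_SEMI_MM)
    )
    lungs = np.zeros(spec.grid_shape, dtype=bool)
    for side in (-1.0, 1.0):
        c = (center[0], center[1], center[2] + side * _LUNG_OFFSET_X_MM)
        lungs |= _ellipsoid((z, y, x), c, _LUNG_SEMI_MM)
    lungs &= inner

    tissue = np.full(spec.grid_shape, -1000.0, dtype=np.float64)
    tissue[body] = spec.body_hu
    n_lung = int(lungs.sum())
    tissue[lungs] = rng.normal(
        spec.parenchyma_mean_hu, spec.parenchyma_sd_hu, n_lung
    )
    noise = rng.normal(0.0, spec.noise_sd_hu, spec.grid_shape) \
        if spec.noise_sd_hu > 0 else np.zeros(spec.grid_shape)

    final = tissue + noise
    below = (final < -950.0) & lungs
    count = int(below.sum())
    target_count = int(np.ceil(spec.target_laa_pct / 100.0 * n_lung))

    lung_idx = np.argwhere(lungs)
    r_vox = np.array([spec.blob_radius_mm / s for s in spec.spacing_mm])
    max_attempts = 20000
    attempts = 0
    while count < target_count:
        attempts += 1
        if attempts > max_attempts:
            raise PhantomError(
                "target not achievable: blob placement budget exhausted"
            )
        cz, cy, cx = lung_idx[rng.integers(0, n_lung)]
        lo = np.maximum(0, np.floor([cz, cy, cx] - r_vox).astype(int))
        hi = np.minimum(
            spec.grid_shape, np.ceil([cz, cy, cx] + r_vox + 1).astype(int)
        )
        box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        bz = (np.arange(lo[0], hi[0]) - cz)[:, None, None] * dz
        by = (np.arange(lo[1], hi[1]) - cy)[None, :, None] * dy
        bx = (np.arange(lo[2], hi[2]) - cx)[None, None, :] * dx
        sphere = (bz**2 + by**2 + bx**2) <= spec.blob_radius_mm**2
        edit = sphere & lungs[box]
        n_edit = int(edit.sum())
        if n_edit == 0:
            continue
        was_below = int((below[box] & edit).sum())
        vals = rng.normal(spec.emphysema_hu_mean, spec.emphysema_hu_sd, n_edit)
        sub = final[box]
        sub[edit] = vals + noise[box][edit]
        now_below = int(((sub < -950.0) & edit).sum())
        below[box] = (final[box] < -950.0) & lungs[box]
        count += now_below - was_below

    np.clip(final, HU_CLAMP[0], HU_CLAMP[1], out=final)
    volume = CTVolume(
        final.astype(np.float32),
        spec.spacing_mm,
        patient_id=f"PHANTOM-{spec.seed}",
        source=f"phantom:seed={spec.seed}",
    )
    mask = LungMask(lungs.astype(np.uint8), spec.spacing_mm)

    true_laa = 100.0 * count / n_lung
    true_mean = float(final[lungs].mean())
    true_label = int(true_laa >= 6.0 and true_mean < -850.0)
    return PhantomTruth(volume, mask, true_laa, true_mean, true_label, spec)


def generate_cohort(
    n: int, prevalence: float, seed: int, base_spec: PhantomSpec | None = None
) -> list[PhantomTruth]:
    """Generate a cohort with a controlled positive-class prevalence.

    ``round(n * prevalence)`` positives draw target LAA in [8, 30]% with
    parenchyma means in [-890, -860] HU; negatives draw target LAA in
    [0, 3]% with parenchyma means in [-830, -790] HU. The gap between the
    class-conditional ranges gives every truth label a decision margin
    against the 6% / -850 HU criteria. Per-phantom seeds derive from the
    cohort seed.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if n < 4:
        raise ValueError("cohort size must be >= 4")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * prevalence))
    cohort: list[PhantomTruth] = []
    for i in range(n):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        positive = i < n_pos
        if positive:
            target = float(rng.uniform(8.0, 30.0))
            pmean = float(rng.uniform(-890.0, -860.0))
        else:
            target = float(rng.uniform(0.0, 3.0))
            pmean = float(rng.uniform(-830.0, -790.0))
        spec = replace(
            base,
            target_laa_pct=target,
            parenchyma_mean_hu=pmean,
            seed=sub_seed,
        )
        truth = generate_phantom(spec)
        truth.volume.patient_id = f"PH-{i:04d}"
        cohort.append(truth)
    return cohort
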