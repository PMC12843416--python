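"""CT volume ingestion and persistence.

Reads DICOM series into Hounsfield-unit volumes with axis order (z, y, x),
selects the most complete series per patient, windows intensities for
visualization, and round-trips the on-disk ``.npy`` + JSON-sidecar format.

Densitometry must always see raw HU: :func:`clip_normalize` returns a new
unit-scaled array and never mutates its input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import SeriesError, SidecarError

HU_WINDOW = (-1000.0, 400.0)
"""Default intensity window, HU: air floor to soft-tissue/bone onset."""


@dataclass
class CTVolume:
    """A 3-D attenuation grid in Hounsfield units.

    Attributes
    ----------
    voxels : np.ndarray
        Attenuation values, axis order (z, y, x).
    spacing_mm : tuple of float
        Voxel spacing (dz, dy, dx) in millimetres, all strictly positive.
    patient_id : str
        Opaque patient identifier.
    source : str
        Provenance descriptor (DICOM series id, phantom seed, file path).
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxel grid must be non-empty and 3-D (z, y, x)")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing_mm
        return dz * dy * dx


@dataclass
class SeriesCatalog:
    """Per-patient inventory of available DICOM series."""

    entries: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("series ids must be unique within a catalog")
        if any(n < 1 for _, n in self.entries):
            raise ValueError("slice counts must be >= 1")


def select_series(catalog: SeriesCatalog) -> str:
    """Pick the series with the most slices (the most complete scan).

    Ties are broken by lexicographically smallest series id so ingestion
    is deterministic.
    """
    if not catalog.entries:
        raise SeriesError("no series in catalog")
    best = min(catalog.entries, key=lambda e: (-e[1], e[0]))
    return best[0]


def _slice_attr(rec, name, default=None):
    val = getattr(rec, name, default)
    if val is None:
        raise SeriesError(f"slice record missing {name}")
    return val


def load_ct_volume(
    dicom_slices: Iterable, patient_id: str = "", source: str = ""
) -> CTVolume:
    """Assemble sorted DICOM slices into a HU volume.

    Accepts any records exposing the pydicom attribute surface:
    ``ImagePositionPatient`` (or ``SliceLocation``), ``RescaleSlope``,
    ``RescaleIntercept``, ``PixelSpacing`` and ``pixel_array``. Slices are
    ordered by ascending z; stored values are mapped through the affine
    rescale ``slope * v + intercept``; dz is the modal inter-slice z-gap,
    which is robust to overlapping reconstructions.
    """
    slices = list(dicom_slices)
    if not slices:
        raise SeriesError("no slices supplied")

    def zpos(rec) -> float:
        ipp = getattr(rec, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(_slice_attr(rec, "SliceLocation"))

    slices.sort(key=zpos)
    zs = np.array([zpos(s) for s in slices], dtype=float)
    if len(zs) > 1 and np.any(np.diff(zs) == 0):
        raise SeriesError("degenerate geometry: duplicate z-positions")

    arrays = []
    shape0 = None
    for rec in slices:
        arr = np.asarray(_slice_attr(rec, "pixel_array"), dtype=np.float32)
        if shape0 is None:
            shape0 = arr.shape
        elif arr.shape != shape0:
            raise SeriesError("inhomogeneous series: pixel grids differ in shape")
        slope = float(getattr(rec, "RescaleSlope", 1.0))
        intercept = float(getattr(rec, "RescaleIntercept", 0.0))
        arrays.append(slope * arr + intercept)

    vol = np.stack(arrays, axis=0)

    if len(zs) > 1:
        gaps = np.round(np.diff(zs), 6)
        vals, counts = np.unique(gaps, return_counts=True)
        dz = float(vals[np.argmax(counts)])
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    ps = getattr(slices[0], "PixelSpacing", (1.0, 1.0))
    dy, dx = float(ps[0]), float(ps[1])

    return CTVolume(vol, (dz, dy, dx), patient_id=patient_id, source=source)


def read_dicom_dir(directory: str | Path, patient_id: str = "") -> CTVolume:
    """Read one patient directory: catalogue the series, keep the one with
    the most slices, and load it as a HU volume."""
    import pydicom

    directory = Path(directory)
    by_series: dict[str, list] = {}
    for path in sorted(directory.rglob("*")):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path, force=True)
        except Exception:
            continue
        if not hasattr(ds, "PixelData"):
            continue
        sid = str(getattr(ds, "SeriesInstanceUID", "unknown"))
        by_series.setdefault(sid, []).append(ds)

    catalog = SeriesCatalog([(sid, len(v)) for sid, v in sorted(by_series.items())])
    chosen = select_series(catalog)
    pid = patient_id or str(getattr(by_series[chosen][0], "PatientID", ""))
    return load_ct_volume(by_series[chosen], patient_id=pid, source=chosen)


def clip_normalize(
    volume: CTVolume | np.ndarray,
    lo: float = HU_WINDOW[0],
    hi: float = HU_WINDOW[1],
) -> np.ndarray:
    """Window HU to [lo, hi] and rescale to the unit interval.

    This is for visualization and backbone input only — quantitative
    densitometry always runs on the raw HU volume. The input is not
    modified.
    """
    if lo >= hi:
        raise ValueError("invalid window: lo must be < hi")
    vox = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    clipped = np.clip(vox.astype(np.float64), lo, hi)
    return (clipped - lo) / (hi - lo)


def save_volume(volume: CTVolume, path: str | Path) -> Path:
    """Persist a volume as ``<stem>.npy`` with a ``<stem>.json`` sidecar.

    The sidecar carries spacing, patient id and source so the array file
    alone is never authoritative.
    """
    path = Path(path)
    stem = path.with_suffix("")
    npy = stem.with_suffix(".npy")
    np.save(npy, volume.voxels)
    sidecar = {
        "spacing_mm": list(volume.spacing_mm),
        "patient_id": volume.patient_id,
        "source": volume.source,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return npy


def load_volume(path: str | Path) -> CTVolume:
    """Load a ``.npy`` volume with its JSON spacing sidecar."""
    stem = Path(path).with_suffix("")
    npy = stem.with_suffix(".npy")
    side = stem.with_suffix(".json")
    if not side.exists():
        raise SidecarError(f"orphan volume: missing sidecar {side}")
    if not npy.exists():
        raise SidecarError(f"missing array file {npy}")
    meta = json.loads(side.read_text())
    if "spacing_mm" not in meta:
        raise SidecarError("invalid sidecar: spacing_mm absent")
    return CTVolume(
        np.load(npy),
        tuple(meta["spacing_mm"]),
        patient_id=meta.get("patient_id", ""),
        source=meta.get("source", ""),
    )
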