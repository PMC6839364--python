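"""Voxel dose grids, organ masks and material phantoms.

Coordinate convention (documented once, used everywhere): arrays are indexed
``[ix, iy, iz]`` with 0-based voxel-centred indices; +x points to the
patient's right, +y anterior-to-posterior, +z inferior-to-superior.  The
default voxel is 2.5 mm isotropic.

Two on-disk dialects are supported:

``portable``
    A self-describing text container (JSON header line + one ``%.17g`` value
    per line).  Round-trips float64 bit-exactly.
``rtdose``
    A genuine DICOM RTDOSE dataset written via pydicom: non-negative 16-bit
    integers with a per-file ``DoseGridScaling`` factor, so reconstruction is
    exact to within half a scaling step (<= max/2^16).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "MATERIALS",
    "MATERIAL_DENSITY_G_CM3",
    "DoseGrid",
    "StructureSet",
    "MaterialPhantom",
    "CouchModel",
    "GridFormatError",
    "mean_organ_dose",
    "mean_organ_doses",
    "label_materials",
    "attach_couch",
    "read_grid",
    "write_grid",
]

#: Material labels in threshold order (air < lung < tissue < bone).
MATERIALS = ("air", "lung", "tissue", "bone")

#: Default mass densities, g/cm^3.
MATERIAL_DENSITY_G_CM3 = {"air": 0.0012, "lung": 0.26, "tissue": 1.0, "bone": 1.85}


class GridFormatError(ValueError):
    """A grid file is corrupt or violates the dialect's contract."""


def _triplet(x) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class DoseGrid:
    """A non-negative 3-D scalar dose field with geometry metadata.

    ``unit`` tags whether values are absolute (``mGy``) or simulator-
    normalised (``per_history``/``per_fluence``); ``axis_order`` records the
    index convention.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "mGy"
    axis_order: str = "xyz"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose grid must be 3-D")
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise ValueError("dose values must be finite and >= 0")
        self.voxel_size_mm = _triplet(self.voxel_size_mm)
        self.origin_mm = _triplet(self.origin_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel size must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        vx, vy, vz = self.voxel_size_mm
        return vx * vy * vz / 1000.0

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "DoseGrid":
        return replace(self, values=values, unit=unit or self.unit)


class StructureSet:
    """Named boolean organ masks congruent with one grid shape."""

    def __init__(self, shape: tuple[int, int, int],
                 masks: Mapping[str, np.ndarray] | None = None):
        self.shape = tuple(int(s) for s in shape)
        self._masks: dict[str, np.ndarray] = {}
        for name, mask in (masks or {}).items():
            self.add(name, mask)

    def add(self, organ_id: str, mask: np.ndarray) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.shape:
            raise ValueError(
                f"mask for {organ_id!r} has shape {mask.shape}, grid is {self.shape}"
            )
        if not mask.any():
            raise ValueError(f"mask for {organ_id!r} is empty")
        self._masks[organ_id] = mask

    def __getitem__(self, organ_id: str) -> np.ndarray:
        return self._masks[organ_id]

    def __contains__(self, organ_id: str) -> bool:
        return organ_id in self._masks

    def __iter__(self) -> Iterator[str]:
        return iter(self._masks)

    def __len__(self) -> int:
        return len(self._masks)

    @property
    def organs(self) -> list[str]:
        return list(self._masks)

    def items(self):
        return self._masks.items()


@dataclass
class MaterialPhantom:
    """Four-material voxel phantom (air / lung / tissue / bone) + density."""

    labels: np.ndarray  # uint8 indices into MATERIALS
    density_g_cm3: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.density_g_cm3 = np.asarray(self.density_g_cm3, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("phantom labels must be 3-D")
        if self.labels.max(initial=0) >= len(MATERIALS):
            raise ValueError("labels must index into the four materials")
        if self.density_g_cm3.shape != self.labels.shape:
            raise ValueError("density field must match label field shape")
        if (self.density_g_cm3 <= 0).any():
            raise ValueError("densities must be positive")
        self.voxel_size_mm = _triplet(self.voxel_size_mm)
        self.origin_mm = _triplet(self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def material_mask(self, material: str) -> np.ndarray:
        return self.labels == MATERIALS.index(material)

    def copy(self) -> "MaterialPhantom":
        return MaterialPhantom(
            self.labels.copy(),
            self.density_g_cm3.copy(),
            self.voxel_size_mm,
            self.origin_mm,
        )


# ---------------------------------------------------------------------------
# operations

def mean_organ_dose(grid: DoseGrid, mask: np.ndarray, organ_id: str = "organ") -> float:
    """Arithmetic mean of the dose over the mask voxels (mGy).

    Raises on an empty or shape-incongruent mask, naming the organ.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError(
            f"mask for {organ_id!r} has shape {mask.shape}, grid is {grid.shape}"
        )
    if not mask.any():
        raise ValueError(f"mask for {organ_id!r} selects no voxels")
    return float(grid.values[mask].mean())


def mean_organ_doses(grid: DoseGrid, structures: StructureSet):
    """Mean dose per structure, as an :class:`~cbctrisk.risk.OrganDoseTable`
    (with volumes from voxel counts)."""
    from .risk import OrganDoseTable

    records = []
    for organ, mask in structures.items():
        records.append(
            (
                organ,
                mean_organ_dose(grid, mask, organ),
                float(mask.sum()) * grid.voxel_volume_cm3,
            )
        )
    return OrganDoseTable.from_records(records)


def label_materials(
    ct_numbers: np.ndarray,
    thresholds: tuple[float, float, float] = (-850.0, -200.0, 120.0),
    densities: Mapping[str, float] = MATERIAL_DENSITY_G_CM3,
    voxel_size_mm=(2.5, 2.5, 2.5),
) -> MaterialPhantom:
    """Label a CT-number field as air/lung/tissue/bone by three cut points.

    A value equal to a cut point is assigned to the upper class.  Densities
    come from a per-material lookup (defaults above); the cut points default
    to conventional HU boundaries and are configuration, not measurement.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) != 3 or not (thresholds[0] < thresholds[1] < thresholds[2]):
        raise ValueError("thresholds must be three strictly increasing cut points")
    ct = np.asarray(ct_numbers, dtype=float)
    labels = np.digitize(ct, thresholds, right=False).astype(np.uint8)
    density = np.empty(ct.shape, dtype=float)
    for idx, mat in enumerate(MATERIALS):
        density[labels == idx] = float(densities[mat])
    return MaterialPhantom(labels, density, voxel_size_mm=voxel_size_mm)


@dataclass(frozen=True)
class CouchModel:
    """Posterior couch-top slab: layers stacked along +y behind the body.

    ``layers`` lists (material, thickness in voxels) from anterior to
    posterior; the slab spans the full x/z extent starting at voxel row
    ``y_start``.
    """

    y_start: int
    layers: tuple[tuple[str, int], ...] = (("tissue", 1), ("lung", 2))

    @property
    def thickness(self) -> int:
        return sum(t for _, t in self.layers)


def attach_couch(phantom: MaterialPhantom, couch: CouchModel) -> MaterialPhantom:
    """Insert the couch slab into the phantom (posterior of the body).

    Couch voxels must currently be air; overlap with body voxels is an
    error.  A zero-thickness couch returns an identical phantom.
    """
    out = phantom.copy()
    y = couch.y_start
    if couch.thickness == 0:
        return out
    if y < 0 or y + couch.thickness > phantom.shape[1]:
        raise ValueError("couch slab extends outside the grid")
    air = MATERIALS.index("air")
    for material, thickness in couch.layers:
        if thickness < 0:
            raise ValueError("layer thickness must be >= 0")
        region = out.labels[:, y : y + thickness, :]
        if (region != air).any():
            raise ValueError("couch overlaps non-air (body) voxels")
        region[...] = MATERIALS.index(material)
        out.density_g_cm3[:, y : y + thickness, :] = MATERIAL_DENSITY_G_CM3[material]
        y += thickness
    return out


# ---------------------------------------------------------------------------
# I/O

_PORTABLE_MAGIC = "cbctrisk-grid"


def write_grid(grid: DoseGrid, path: str | Path, dialect: str = "portable") -> None:
    """Write a dose grid in the ``portable`` or ``rtdose`` dialect."""
    if dialect == "portable":
        _write_portable(grid, Path(path))
    elif dialect == "rtdose":
        _write_rtdose(grid, Path(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_grid(path: str | Path, dialect: str = "portable") -> DoseGrid:
    """Read a dose grid written by :func:`write_grid`."""
    if dialect == "portable":
        return _read_portable(Path(path))
    if dialect == "rtdose":
        return _read_rtdose(Path(path))
    raise ValueError(f"unknown dialect {dialect!r}")


def _write_portable(grid: DoseGrid, path: Path) -> None:
    header = {
        "format": _PORTABLE_MAGIC,
        "version": 1,
        "shape": list(grid.shape),
        "voxel_size_mm": list(grid.voxel_size_mm),
        "origin_mm": list(grid.origin_mm),
        "unit": grid.unit,
        "axis_order": grid.axis_order,
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        # 17 significant digits round-trip IEEE float64 exactly
        np.savetxt(fh, grid.values.ravel(order="C"), fmt="%.17g")


def _read_portable(path: Path) -> DoseGrid:
    with open(path) as fh:
        first = fh.readline()
        try:
            header = json.loads(first)
        except json.JSONDecodeError as exc:
            raise GridFormatError(f"corrupt portable-grid header in {path}") from exc
        if header.get("format") != _PORTABLE_MAGIC:
            raise GridFormatError(f"{path} is not a portable grid container")
        values = np.loadtxt(fh, dtype=float)
    shape = tuple(header["shape"])
    if values.size != int(np.prod(shape)):
        raise GridFormatError(
            f"{path}: payload has {values.size} values, header says {shape}"
        )
    return DoseGrid(
        values.reshape(shape),
        voxel_size_mm=tuple(header["voxel_size_mm"]),
        origin_mm=tuple(header["origin_mm"]),
        unit=header.get("unit", "mGy"),
        axis_order=header.get("axis_order", "xyz"),
    )


def _write_rtdose(grid: DoseGrid, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    if grid.unit != "mGy":
        raise ValueError("rtdose dialect stores absolute dose; grid unit must be mGy")
    peak = float(grid.values.max())
    # scaling chosen so the 16-bit integer range is fully used
    scaling_gy = (peak / 1000.0) / 65535.0 if peak > 0 else 1.0e-7
    pixels = np.round((grid.values / 1000.0) / scaling_gy).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.2")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling_gy
    nx, ny, nz = grid.shape
    ds.Rows = ny
    ds.Columns = nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [grid.voxel_size_mm[1], grid.voxel_size_mm[0]]
    ds.SliceThickness = grid.voxel_size_mm[2]
    ds.GridFrameOffsetVector = [i * grid.voxel_size_mm[2] for i in range(nz)]
    ds.ImagePositionPatient = list(grid.origin_mm)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    # DICOM frames are z-major: (frame, row, col) = (z, y, x)
    ds.PixelData = np.ascontiguousarray(pixels.transpose(2, 1, 0)).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def _read_rtdose(path: Path) -> DoseGrid:
    import pydicom

    try:
        ds = pydicom.dcmread(str(path))
    except Exception as exc:  # pydicom raises a zoo of parse errors
        raise GridFormatError(f"cannot parse {path} as DICOM") from exc
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise GridFormatError(f"{path} is not an RTDOSE dataset")
    scaling = float(ds.DoseGridScaling)
    if scaling < 0:
        raise GridFormatError("negative DoseGridScaling")
    frames = ds.pixel_array  # (nz, ny, nx) or (ny, nx)
    if frames.ndim == 2:
        frames = frames[None, ...]
    values = frames.transpose(2, 1, 0).astype(float) * scaling * 1000.0  # Gy -> mGy
    voxel = (
        float(ds.PixelSpacing[1]),
        float(ds.PixelSpacing[0]),
        float(ds.SliceThickness),
    )
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    return DoseGrid(values, voxel_size_mm=voxel, origin_mm=origin, unit="mGy")
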