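"""Volume, mask and table I/O plus the shared grid/coordinate contract.

All modules exchange 3-D scalar grids through :class:`Volume`. The axis
convention is fixed package-wide:

* axis 0 — depth (rows; increasing away from the ultrasound transducer),
* axis 1 — lateral width (columns),
* axis 2 — longitudinal slice index (axial cross-sections of the shell).

Physical coordinates are ``index * voxel_mm + origin_mm``; every physical
quantity downstream is in mm / mm². Operations consuming two grids must call
:func:`assert_same_grid` first.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Volume",
    "BinaryMask",
    "FrameGeometry",
    "assert_same_grid",
    "load_volume",
    "write_volume",
    "load_rigid_transform",
    "apply_rigid_transform",
    "write_slice_table",
    "read_slice_table",
    "read_slice_records",
]


@dataclasses.dataclass
class Volume:
    """A 3-D scalar grid with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (depth, width, slices)
    voxel_mm : per-axis positive spacing in mm
    origin_mm : physical coordinate of voxel (0, 0, 0)
    """

    values: np.ndarray
    voxel_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"Volume must be 3-D, got shape {self.values.shape}")
        self.voxel_mm = tuple(float(v) for v in np.broadcast_to(self.voxel_mm, (3,)))
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_mm}")
        self.origin_mm = tuple(float(v) for v in np.broadcast_to(self.origin_mm, (3,)))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_coords_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.values.shape[axis]
        return self.origin_mm[axis] + self.voxel_mm[axis] * np.arange(n)

    def same_grid_as(self, other: "Volume") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.voxel_mm, other.voxel_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


class BinaryMask(Volume):
    """A {0,1} annotation sharing the grid of the volume it describes."""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("BinaryMask values must be in {0, 1}")
            vals = vals.astype(bool)
        self.values = vals
        super().__post_init__()


def assert_same_grid(a: Volume, b: Volume) -> None:
    if not a.same_grid_as(b):
        raise ValueError(
            "grid mismatch: "
            f"shapes {a.values.shape} vs {b.values.shape}, "
            f"spacing {a.voxel_mm} vs {b.voxel_mm}, "
            f"origin {a.origin_mm} vs {b.origin_mm}"
        )


@dataclasses.dataclass(frozen=True)
class FrameGeometry:
    """B-mode frame extent; its area normalizes the new-bone bulk marker."""

    fov_width_mm: float
    fov_depth_mm: float

    def __post_init__(self) -> None:
        if self.fov_width_mm <= 0 or self.fov_depth_mm <= 0:
            raise ValueError("FOV extents must be positive")

    @property
    def fov_area_mm2(self) -> float:
        return self.fov_width_mm * self.fov_depth_mm

    @classmethod
    def from_volume(cls, vol: Volume) -> "FrameGeometry":
        nd, nw, _ = vol.values.shape
        return cls(fov_width_mm=nw * vol.voxel_mm[1], fov_depth_mm=nd * vol.voxel_mm[0])


# ---------------------------------------------------------------------------
# volume file I/O


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(".nii") or path.name.endswith(".nii.gz")


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in (".tif", ".tiff")


def load_volume(path: str | Path, spacing_mm: Sequence[float] | None = None) -> Volume:
    """Read a NIfTI-1 or multipage-TIFF volume.

    Spacing is taken from the file header. A TIFF without resolvable spacing
    metadata requires an explicit ``spacing_mm`` — spacing is never silently
    assumed to be 1 mm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
        zooms = img.header.get_zooms()[:3]
        if spacing_mm is not None:
            zooms = spacing_mm
        if any(z <= 0 for z in zooms):
            raise ValueError(f"non-positive spacing in header: {zooms}")
        return Volume(data, tuple(float(z) for z in zooms))
    if _is_tiff(path):
        with tifffile.TiffFile(str(path)) as tif:
            data = tif.asarray()
            spacing = spacing_mm
            if spacing is None:
                spacing = _tiff_spacing(tif)
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D TIFF stack, got shape {data.shape}")
        if spacing is None:
            raise ValueError(
                f"{path}: no voxel spacing in TIFF metadata; pass spacing_mm explicitly"
            )
        # tifffile yields (slices, depth, width); restore (depth, width, slices)
        return Volume(np.moveaxis(data, 0, 2).astype(np.float64), tuple(spacing))
    raise ValueError(f"unsupported volume format: {path}")


def _tiff_spacing(tif: "tifffile.TiffFile") -> tuple[float, float, float] | None:
    meta = tif.imagej_metadata or {}
    z = meta.get("spacing")
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    except KeyError:
        return None
    if z is None or not xres[0] or not yres[0]:
        return None
    dy = yres[1] / yres[0]  # rows = depth
    dx = xres[1] / xres[0]  # columns = width
    return (float(dy), float(dx), float(z))


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write NIfTI-1 (.nii/.nii.gz) or ImageJ TIFF (.tif), spacing in header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        affine = np.diag(list(vol.voxel_mm) + [1.0])
        affine[:3, 3] = vol.origin_mm
        img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine)
        img.header.set_zooms(vol.voxel_mm)
        nib.save(img, str(path))
        return
    if _is_tiff(path):
        dd, dw, dz = vol.voxel_mm
        tifffile.imwrite(
            str(path),
            np.moveaxis(vol.values, 2, 0).astype(np.float32),
            imagej=True,
            resolution=(1.0 / dw, 1.0 / dd),
            metadata={"spacing": dz, "unit": "mm"},
        )
        return
    raise ValueError(f"unsupported volume format: {path}")


# ---------------------------------------------------------------------------
# rigid co-registration transforms (supplied externally, e.g. from manual
# alignment in a viewer; this package does not register images itself)


def load_rigid_transform(path: str | Path) -> np.ndarray:
    """Load a 4x4 rigid transform (mm coordinates) from JSON {"matrix": [[...]]}."""
    with open(path) as fh:
        obj = json.load(fh)
    T = np.asarray(obj["matrix"], dtype=float)
    if T.shape != (4, 4):
        raise ValueError(f"transform matrix must be 4x4, got {T.shape}")
    R = T[:3, :3]
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
        raise ValueError("transform rotation block is not orthonormal")
    return T


def apply_rigid_transform(vol: Volume, T: np.ndarray, order: int = 1) -> Volume:
    """Resample ``vol`` under a rigid transform of physical (mm) coordinates.

    ``T`` maps input-frame mm coordinates to output-frame mm coordinates; the
    output grid equals the input grid.
    """
    from scipy import ndimage

    S = np.diag(vol.voxel_mm)
    o = np.asarray(vol.origin_mm)
    Tinv = np.linalg.inv(T)
    # output index -> output mm -> input mm -> input index
    A = np.linalg.inv(S) @ Tinv[:3, :3] @ S
    b = np.linalg.inv(S) @ (Tinv[:3, :3] @ o + Tinv[:3, 3] - o)
    out = ndimage.affine_transform(vol.values, A, offset=b, order=order)
    return Volume(out, vol.voxel_mm, vol.origin_mm)


# ---------------------------------------------------------------------------
# per-slice morphometry tables

TABLE_COLUMNS = [
    "scan_id",
    "slice_z_mm",
    "region",
    "nbb_area_mm2",
    "nbs_length_mm",
    "nbc_length_mm",
    "nbb_norm_pct",
    "nbs_norm",
    "nbc_norm_pct",
]


def write_slice_table(records: Sequence, path: str | Path) -> None:
    """Write per-slice morphometry records to CSV (one row per slice).

    CSV dialect is fixed: comma separator, '.' decimal, UTF-8, header row.
    """
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


def read_slice_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"slice table {path} missing columns: {missing}")
    return df


def read_slice_records(path: str | Path) -> list:
    """Read a per-slice CSV back into SliceMorphometry records."""
    from .morphometry import SliceMorphometry

    df = read_slice_table(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            SliceMorphometry(
                slice_z_mm=float(row.slice_z_mm),
                nbb_area_mm2=float(row.nbb_area_mm2),
                nbs_length_mm=float(row.nbs_length_mm),
                nbc_length_mm=float(row.nbc_length_mm),
                nbb_norm_pct=float(row.nbb_norm_pct),
                nbs_norm=float(row.nbs_norm),
                nbc_norm_pct=float(row.nbc_norm_pct),
                region=str(row.region),
                scan_id="" if pd.isna(row.scan_id) else str(row.scan_id),
            )
        )
    return out
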