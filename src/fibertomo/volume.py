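"""3D scalar volumes with physical voxel sizes, and MRC/TIFF round-trip I/O.

Conventions used throughout the package:

* array axes are ``(z, y, x)``, 0-based;
* physical coordinates are in nanometres;
* the centre of voxel ``(i, j, k)`` sits at ``((i + 0.5) * dz, (j + 0.5) * dy,
  (k + 0.5) * dx)`` plus the volume origin.

MRC-style maps are written through :mod:`gemmi` (CCP4/MRC2014 layout); the
header cell stores Ångström, i.e. ten times the nanometre voxel size.
"""

from __future__ import annotations

import os

import numpy as np

from .errors import VolumeMismatchError

__all__ = ["Volume", "read_volume", "write_volume"]

_NM_PER_ANGSTROM = 0.1


class Volume:
    """A 3D scalar grid with per-axis physical voxel size.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``; must be finite everywhere.
    voxel_size
        Physical size of one voxel in nm, per axis ``(dz, dy, dx)``.
    origin
        Physical offset of the grid corner in nm, per axis.
    """

    def __init__(self, data, voxel_size, origin=(0.0, 0.0, 0.0)):
        data = np.asarray(data)
        if data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {data.shape}")
        voxel_size = _as_triple(voxel_size)
        if any(v <= 0 for v in voxel_size):
            raise ValueError(f"voxel_size must be strictly positive, got {voxel_size}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")
        self.data = data
        self.voxel_size = voxel_size
        self.origin = _as_triple(origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def physical_extent(self) -> tuple[float, float, float]:
        """Slab dimensions in nm, per axis."""
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates (nm) of voxel centres along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def index_to_nm(self, indices: np.ndarray) -> np.ndarray:
        """Convert ``(N, 3)`` voxel indices to physical voxel-centre coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (idx + 0.5) * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def same_geometry(self, other: "Volume", atol: float = 1e-9) -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size, atol=atol
        )

    def require_same_geometry(self, other: "Volume") -> None:
        if not self.same_geometry(other):
            raise VolumeMismatchError(
                f"volume geometry mismatch: {self.shape}@{self.voxel_size} vs "
                f"{other.shape}@{other.voxel_size}"
            )


def _as_triple(value) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (3,))
    return (float(arr[0]), float(arr[1]), float(arr[2]))


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a volume as MRC/CCP4 (``.mrc``, ``.map``) or multi-page TIFF.

    The format is chosen from the file extension. TIFF files carry the voxel
    size in ImageJ-style metadata (``spacing`` for z, resolution for x/y).
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".mrc", ".map", ".ccp4"):
        _write_mrc(volume, path)
    elif ext in (".tif", ".tiff"):
        _write_tiff(volume, path)
    else:
        raise ValueError(f"unsupported volume format: {ext!r}")


def read_volume(path: str | os.PathLike, voxel_size=None) -> Volume:
    """Read an MRC/CCP4 or multi-page TIFF volume.

    ``voxel_size`` (nm, scalar or per-axis) overrides whatever the file header
    declares; TIFF files without usable metadata require it.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".mrc", ".map", ".ccp4"):
        return _read_mrc(path, voxel_size)
    if ext in (".tif", ".tiff"):
        return _read_tiff(path, voxel_size)
    raise ValueError(f"unsupported volume format: {ext!r}")


def _write_mrc(volume: Volume, path: str) -> None:
    import gemmi

    # gemmi grids are (x, y, z) fastest-to-slowest; our arrays are (z, y, x).
    arr = np.ascontiguousarray(volume.data.astype(np.float32).transpose(2, 1, 0))
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    nz, ny, nx = volume.shape
    dz, dy, dx = volume.voxel_size
    m.grid.set_unit_cell(
        gemmi.UnitCell(nx * dx / _NM_PER_ANGSTROM, ny * dy / _NM_PER_ANGSTROM,
                       nz * dz / _NM_PER_ANGSTROM, 90.0, 90.0, 90.0)
    )
    m.update_ccp4_header()
    m.write_ccp4_map(path)


def _read_mrc(path: str, voxel_size) -> Volume:
    import gemmi

    m = gemmi.read_ccp4_map(path)
    data = np.array(m.grid, copy=True).transpose(2, 1, 0)
    if voxel_size is None:
        cell = m.grid.unit_cell
        voxel_size = (
            cell.c / m.grid.nw * _NM_PER_ANGSTROM,
            cell.b / m.grid.nv * _NM_PER_ANGSTROM,
            cell.a / m.grid.nu * _NM_PER_ANGSTROM,
        )
    return Volume(data, voxel_size)


def _write_tiff(volume: Volume, path: str) -> None:
    import tifffile

    dz, dy, dx = volume.voxel_size
    # ImageJ metadata: spacing is the z step; x/y resolution in pixels per nm.
    tifffile.imwrite(
        path,
        volume.data.astype(np.float32),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "nm", "axes": "ZYX"},
    )


def _read_tiff(path: str, voxel_size) -> Volume:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        if voxel_size is None:
            voxel_size = _tiff_voxel_size(tif)
    if data.ndim == 2:
        data = data[None]
    if voxel_size is None:
        raise ValueError(
            f"{path}: no voxel size metadata; pass voxel_size= explicitly"
        )
    return Volume(data, voxel_size)


def _tiff_voxel_size(tif) -> tuple[float, float, float] | None:
    meta = tif.imagej_metadata or {}
    dz = meta.get("spacing")
    page = tif.pages[0]
    tags = {t.name: t.value for t in page.tags.values()}
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    if dz is None or xres is None or yres is None:
        return None
    dx = xres[1] / xres[0]
    dy = yres[1] / yres[0]
    return (float(dz), float(dy), float(dx))
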