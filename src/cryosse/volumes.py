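"""Density and label volumes, MRC I/O, and box-crop / padding geometry.

Grids are axis-aligned with isotropic voxel spacing in Å.  Voxel index
``(i, j, k)`` maps to the *center* of the voxel at Cartesian position
``origin + index * spacing``; index ranges are 0-based and half-open
throughout.  All internal computation is done on a 1 Å isotropic grid by
default (anisotropic inputs are resampled on load).

The box-crop convention mirrors how chain-sized subregions are prepared
for the segmentation network: the Cα bounding box of the structure is
expanded by half the padding amount on each side (34 Å total per axis by
default), giving the network room to develop its ~35 Å depth of field;
evaluation and final output always remove that padding again
(:func:`center_box`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import gemmi
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Default total padding per axis in Å (half of it applied per side).
DEFAULT_PAD_ANGSTROM = 34.0

#: Default isotropic working grid spacing in Å.
DEFAULT_SPACING = 1.0


class VolumeFormatError(ValueError):
    """Raised for malformed or unsupported volume files."""


def _as_float_triple(x) -> Tuple[float, float, float]:
    a = np.asarray(x, dtype=float).reshape(3)
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass
class DensityMap:
    """A 3D scalar density grid.

    Attributes
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities (arbitrary units), float32.
    spacing : float
        Isotropic voxel edge length in Å.
    origin : (float, float, float)
        Cartesian position (Å) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: float = DEFAULT_SPACING
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("density grid must be 3D with all dims >= 1")
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")
        self.origin = _as_float_triple(self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def voxel_center(self, index) -> np.ndarray:
        """World coordinate (Å) of a voxel index (may be fractional)."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * self.spacing

    def world_to_index(self, xyz) -> np.ndarray:
        return (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / self.spacing


@dataclass
class LabelMap:
    """Per-voxel class grid on the same lattice as a :class:`DensityMap`.

    Classes: 0 = background, 1 = helix, 2 = sheet.
    """

    classes: np.ndarray
    spacing: float = DEFAULT_SPACING
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    BACKGROUND = 0
    HELIX = 1
    SHEET = 2

    def __post_init__(self):
        arr = np.asarray(self.classes)
        if arr.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.isin(arr, (0, 1, 2)).all():
            raise ValueError("label entries must be in {0, 1, 2}")
        self.classes = arr.astype(np.uint8)
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        self.origin = _as_float_triple(self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.classes.shape

    def voxel_center(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * self.spacing

    def class_counts(self) -> dict:
        """Voxel count per class id."""
        return {int(c): int(n) for c, n in zip(*np.unique(self.classes, return_counts=True))}


Volume = Union[DensityMap, LabelMap]


@dataclass
class BoxSpec:
    """A cropped box and the padding applied around its center region.

    ``lower``/``upper`` are 0-based half-open voxel bounds of the crop in
    the source grid; ``pad_lower``/``pad_upper`` are the per-side padding
    voxel counts actually applied on each axis (they may be asymmetric
    when the requested padding was clipped at the map boundary).
    """

    lower: Tuple[int, int, int]
    upper: Tuple[int, int, int]
    pad_lower: Tuple[int, int, int] = (0, 0, 0)
    pad_upper: Tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self):
        self.lower = tuple(int(v) for v in self.lower)
        self.upper = tuple(int(v) for v in self.upper)
        self.pad_lower = tuple(int(v) for v in self.pad_lower)
        self.pad_upper = tuple(int(v) for v in self.pad_upper)
        for lo, up in zip(self.lower, self.upper):
            if not lo < up:
                raise ValueError("BoxSpec requires lower < upper on every axis")
        if min(self.pad_lower) < 0 or min(self.pad_upper) < 0:
            raise ValueError("padding must be >= 0")
        for lo, up, pl, pu in zip(self.lower, self.upper, self.pad_lower, self.pad_upper):
            if (up - lo) - pl - pu < 1:
                raise ValueError("center box (bounds minus padding) must be non-empty")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(u - l for l, u in zip(self.lower, self.upper))

    def to_json(self, path) -> None:
        data = {
            "lower": list(self.lower),
            "upper": list(self.upper),
            "pad": [[pl, pu] for pl, pu in zip(self.pad_lower, self.pad_upper)],
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path) -> "BoxSpec":
        data = json.loads(Path(path).read_text())
        pads = data["pad"]
        return cls(
            lower=data["lower"],
            upper=data["upper"],
            pad_lower=[p[0] for p in pads],
            pad_upper=[p[1] for p in pads],
        )


# ---------------------------------------------------------------------------
# MRC2014 / CCP4 I/O (via gemmi)
# ---------------------------------------------------------------------------

def read_density(path, target_spacing: float | None = None) -> DensityMap:
    """Read an MRC2014/CCP4 volume.

    The axis order is normalised by gemmi according to the header's
    mapc/mapr/maps fields.  Anisotropic voxel spacing is resampled to the
    smallest axis spacing (a warning is logged) so that all downstream
    geometry can assume an isotropic grid.

    Parameters
    ----------
    path : path-like
    target_spacing : float, optional
        If given, additionally resample to this spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"))
    except (RuntimeError, ValueError) as exc:
        raise VolumeFormatError(f"not a valid MRC/CCP4 volume: {path}: {exc}") from exc
    values = np.array(m.grid, copy=True).astype(np.float32)
    if not np.all(np.isfinite(values)):
        raise VolumeFormatError(f"volume contains non-finite voxels: {path}")
    sx, sy, sz = m.grid.spacing
    origin = (m.header_float(50), m.header_float(51), m.header_float(52))
    if origin == (0.0, 0.0, 0.0):
        # MRC2014 allows NC/NR/NS-start addressing instead of ORIGIN
        nstart = (m.header_i32(5), m.header_i32(6), m.header_i32(7))
        origin = (nstart[0] * sx, nstart[1] * sy, nstart[2] * sz)
    spacings = np.array([sx, sy, sz], dtype=float)
    if np.ptp(spacings) > 1e-4 * spacings.min():
        logger.warning(
            "anisotropic voxel spacing %s in %s; resampling to isotropic %.4g Å",
            tuple(spacings), path, spacings.min(),
        )
        dm = _resample_aniso(values, spacings, origin, float(spacings.min()))
    else:
        dm = DensityMap(values, float(spacings.mean()), origin)
    if target_spacing is not None:
        dm = resample(dm, target_spacing)
    return dm


def read_labels(path) -> LabelMap:
    """Read a label volume previously written by :func:`write_density`."""
    dm = read_density(path)
    classes = np.rint(dm.values).astype(np.int64)
    return LabelMap(classes, dm.spacing, dm.origin)


def write_density(vol: Volume, path) -> None:
    """Write a density or label grid as an MRC2014 file.

    Label maps are written as integer-valued float32 volumes (exact for
    classes {0, 1, 2}); the round trip through :func:`read_labels` is
    lossless.
    """
    if isinstance(vol, LabelMap):
        values = vol.classes.astype(np.float32)
    else:
        values = vol.values
    if not np.all(np.isfinite(values)):
        raise ValueError("refusing to write non-finite voxel values")
    arr = np.ascontiguousarray(values, dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    s = vol.spacing
    m.grid.unit_cell = gemmi.UnitCell(
        arr.shape[0] * s, arr.shape[1] * s, arr.shape[2] * s, 90.0, 90.0, 90.0
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), vol.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _resample_aniso(values, spacings, origin, target: float) -> DensityMap:
    old_shape = np.array(values.shape)
    extent = (old_shape - 1) * spacings  # between first and last voxel centers
    new_shape = np.floor(extent / target + 1e-9).astype(int) + 1
    grids = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(new_shape, spacings)], indexing="ij"
    )
    out = ndimage.map_coordinates(values, np.stack(grids), order=1, mode="nearest")
    return DensityMap(out.astype(np.float32), target, origin)


def resample(dm: DensityMap, target_spacing: float) -> DensityMap:
    """Trilinear resample onto a grid with the requested isotropic spacing.

    The new grid covers the same physical extent (first voxel center kept
    at the original origin).  Identity when the spacing is unchanged.
    """
    if not target_spacing > 0:
        raise ValueError("target_spacing must be > 0")
    if abs(target_spacing - dm.spacing) < 1e-12:
        return DensityMap(dm.values.copy(), dm.spacing, dm.origin)
    return _resample_aniso(
        dm.values, np.full(3, dm.spacing), dm.origin, float(target_spacing)
    )


# ---------------------------------------------------------------------------
# Box cropping
# ---------------------------------------------------------------------------

def crop_box(dm: DensityMap, structure, pad_angstrom: float = DEFAULT_PAD_ANGSTROM):
    """Crop the Cα bounding box of *structure* plus padding out of *dm*.

    The bounding box of the Cα atoms (in voxel index space) is expanded
    by ``pad_angstrom / 2`` on each side — i.e. ``pad_angstrom`` total per
    axis — then clipped to the map bounds.  The returned
    :class:`BoxSpec` records the per-side padding actually applied, so
    :func:`center_box` can remove it even when clipping made it
    asymmetric.

    Returns
    -------
    (DensityMap, BoxSpec)
        The cropped map (origin updated so voxel world coordinates are
        unchanged) and the box description in source-grid indices.
    """
    ca = structure.ca_array()
    if ca.size == 0:
        raise ValueError("cannot crop around an empty structure")
    if pad_angstrom < 0:
        raise ValueError("padding must be >= 0")
    idx = dm.world_to_index(ca)
    lo = np.floor(idx.min(axis=0) + 1e-9).astype(int)
    up = np.floor(idx.max(axis=0) + 1e-9).astype(int) + 1  # half-open
    shape = np.array(dm.shape)
    lo = np.clip(lo, 0, shape - 1)
    up = np.clip(up, lo + 1, shape)
    if np.any(lo >= shape) or np.any(up <= 0):
        raise ValueError("structure lies outside the map extent")
    pad_vox = int(round(pad_angstrom / 2.0 / dm.spacing))
    lo_p = np.maximum(lo - pad_vox, 0)
    up_p = np.minimum(up + pad_vox, shape)
    pad_lower = lo - lo_p
    pad_upper = up_p - up
    box = BoxSpec(tuple(lo_p), tuple(up_p), tuple(pad_lower), tuple(pad_upper))
    sub = dm.values[lo_p[0]:up_p[0], lo_p[1]:up_p[1], lo_p[2]:up_p[2]]
    new_origin = tuple(np.asarray(dm.origin) + lo_p * dm.spacing)
    return DensityMap(sub.copy(), dm.spacing, new_origin), box


def center_box(vol: Volume, box: BoxSpec) -> Volume:
    """Remove the padding of *box* from a cropped volume.

    *vol* must be the cropped volume the box describes (shape equal to
    ``box.shape``).  Identity for zero padding.
    """
    arr = vol.classes if isinstance(vol, LabelMap) else vol.values
    if arr.shape != box.shape:
        raise ValueError(f"volume shape {arr.shape} != box shape {box.shape}")
    sl = []
    for n, pl, pu in zip(arr.shape, box.pad_lower, box.pad_upper):
        if pl + pu >= n:
            raise ValueError("padding consumes the whole extent on an axis")
        sl.append(slice(pl, n - pu))
    sub = arr[tuple(sl)].copy()
    new_origin = tuple(
        np.asarray(vol.origin) + np.array(box.pad_lower) * vol.spacing
    )
    if isinstance(vol, LabelMap):
        return LabelMap(sub, vol.spacing, new_origin)
    return DensityMap(sub, vol.spacing, new_origin)


def center_box_mask(box: BoxSpec) -> np.ndarray:
    """Boolean mask over the cropped volume that is True inside the center box."""
    mask = np.zeros(box.shape, dtype=bool)
    sl = tuple(
        slice(pl, n - pu)
        for n, pl, pu in zip(box.shape, box.pad_lower, box.pad_upper)
    )
    mask[sl] = True
    return mask
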