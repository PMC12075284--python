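"""Volumetric containers, NIfTI I/O, and grid resampling.

All grids in this package follow one fixed axis convention:

* axis 0 = x, left -> right
* axis 1 = y, posterior -> anterior
* axis 2 = z, inferior -> superior

i.e. RAS voxel axes with 0-based indices.  The physical coordinate of voxel
``(i, j, k)`` is ``origin_mm + (i, j, k) * spacing_mm`` per axis.  Files whose
orientation metadata differs are reoriented on read (axis permutations and
flips only; no resampling).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume3D",
    "LabelVolume",
    "MaskVolume",
    "AnyVolume",
    "read_volume",
    "write_volume",
    "resample",
]


def _check_grid(data: np.ndarray, spacing_mm) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D grid, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"every dimension must be >= 1, got shape {data.shape}")
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.shape != (3,) or not np.all(spacing > 0):
        raise ValueError(f"spacing_mm must be 3 positive lengths, got {spacing_mm}")


@dataclass
class Volume3D:
    """Scalar 3-D grid with voxel spacing and physical origin (mm)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        _check_grid(self.data, self.spacing_mm)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def coords_mm(self, index) -> np.ndarray:
        """Physical coordinate of voxel ``index`` (origin + i * spacing)."""
        return np.asarray(self.origin_mm) + np.asarray(index) * np.asarray(self.spacing_mm)


@dataclass
class LabelVolume:
    """Integer label grid; 0 is background; nonzero labels are named."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    label_names: Mapping[int, str] = field(default_factory=dict)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("label data must be integer-valued")
            arr = np.round(arr).astype(np.int32)
        if arr.min() < 0:
            raise ValueError("label data must be non-negative")
        self.data = arr
        _check_grid(self.data, self.spacing_mm)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        present = set(int(v) for v in np.unique(self.data)) - {0}
        if not self.label_names:
            self.label_names = {v: f"label_{v}" for v in sorted(present)}
        else:
            self.label_names = {int(k): str(v) for k, v in self.label_names.items()}
            missing = present - set(self.label_names)
            if missing:
                raise ValueError(f"labels present but unnamed: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def mask(self, label_ids) -> "MaskVolume":
        """Boolean mask of one or more label ids."""
        ids = np.atleast_1d(np.asarray(label_ids, dtype=int))
        return MaskVolume(np.isin(self.data, ids), self.spacing_mm, self.origin_mm)


@dataclass
class MaskVolume:
    """Boolean 3-D grid on the shared voxel lattice."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        _check_grid(self.data, self.spacing_mm)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


AnyVolume = Union[Volume3D, LabelVolume, MaskVolume]

Kind = Literal["scalar", "label", "mask"]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".labels.json")
    return path.with_suffix(".labels.json")


def read_volume(path, kind: Kind = "scalar") -> AnyVolume:
    """Read a NIfTI volume, reorienting it into the package's RAS convention.

    Parameters
    ----------
    path:
        A ``.nii`` / ``.nii.gz`` file.
    kind:
        ``"scalar"`` -> :class:`Volume3D`, ``"label"`` -> :class:`LabelVolume`
        (a ``<stem>.labels.json`` sidecar supplies names when present),
        ``"mask"`` -> :class:`MaskVolume`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)  # RAS+ == our axis convention
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D payload, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if kind == "scalar":
        return Volume3D(data.astype(float), spacing, origin)
    if kind == "label":
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: non-integer data for label kind")
        names = {}
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            names = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        return LabelVolume(np.round(data).astype(np.int32), spacing, names, origin)
    if kind == "mask":
        return MaskVolume(data > 0, spacing, origin)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(vol: AnyVolume, path) -> Path:
    """Write a volume as NIfTI (lossless for integer/boolean kinds).

    A :class:`LabelVolume` additionally writes its name map as a
    ``<stem>.labels.json`` sidecar.
    """
    path = Path(path)
    _check_grid(np.asarray(vol.data), vol.spacing_mm)
    if isinstance(vol, MaskVolume):
        payload = vol.data.astype(np.uint8)
    elif isinstance(vol, LabelVolume):
        payload = vol.data.astype(np.int32)
    else:
        payload = vol.data.astype(np.float64)
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing_mm
    affine[:3, 3] = vol.origin_mm
    img = nib.Nifti1Image(payload, affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    if isinstance(vol, LabelVolume):
        _sidecar_path(path).write_text(
            json.dumps({str(k): v for k, v in vol.label_names.items()}, indent=1)
        )
    return path


def resample(vol: AnyVolume, new_spacing_mm, mode: Literal["linear", "nearest"] = "linear") -> AnyVolume:
    """Resample onto a new spacing, preserving the physical extent.

    The output grid has ``ceil(n * spacing / new_spacing)`` voxels per axis
    (half-open extent convention) and the same origin; output voxel ``i``
    samples the input at physical position ``origin + i * new_spacing``.
    Label and mask volumes require ``mode="nearest"``.
    """
    new_spacing = np.asarray(new_spacing_mm, dtype=float)
    if new_spacing.shape != (3,) or not np.all(new_spacing > 0):
        raise ValueError(f"new_spacing_mm must be 3 positive lengths, got {new_spacing_mm}")
    if isinstance(vol, (LabelVolume, MaskVolume)) and mode != "nearest":
        raise ValueError(f"{type(vol).__name__} requires mode='nearest'")

    old_spacing = np.asarray(vol.spacing_mm)
    if np.allclose(new_spacing, old_spacing):
        return vol
    shape = np.asarray(vol.shape)
    new_shape = np.maximum(1, np.ceil(shape * old_spacing / new_spacing - 1e-9).astype(int))
    # fractional input indices of each output sample
    axes = [np.arange(n) * new_spacing[a] / old_spacing[a] for a, n in enumerate(new_shape)]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack(grid)
    order = 1 if mode == "linear" else 0
    src = vol.data.astype(float)
    out = ndimage.map_coordinates(src, coords, order=order, mode="nearest")
    spacing = tuple(float(s) for s in new_spacing)
    if isinstance(vol, Volume3D):
        return Volume3D(out, spacing, vol.origin_mm)
    if isinstance(vol, LabelVolume):
        return LabelVolume(np.round(out).astype(np.int32), spacing, dict(vol.label_names), vol.origin_mm)
    return MaskVolume(out > 0.5, spacing, vol.origin_mm)


def require_same_grid(*vols: AnyVolume) -> None:
    """Raise if the given volumes do not share shape and spacing."""
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape:
            raise ValueError(f"grid shape mismatch: {v.shape} vs {ref.shape}")
        if not np.allclose(v.spacing_mm, ref.spacing_mm):
            raise ValueError(f"grid spacing mismatch: {v.spacing_mm} vs {ref.spacing_mm}")
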