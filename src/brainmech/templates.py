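"""Group-average templates from pre-aligned cohorts.

Voxelwise averaging with per-voxel contribution counts, Laplacian edge
sharpening, directional thinning for the dural membranes (falx thinned
along left-right, tentorium along inferior-superior), and brain/ventricle
volume metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, MaskVolume, Volume3D, require_same_grid

__all__ = [
    "GroupTemplate",
    "VolumeMetrics",
    "average_images",
    "laplacian_sharpen",
    "union_and_thin",
    "compute_volumes",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class GroupTemplate:
    """Voxelwise mean/SD/count of a cohort, with a validity mask."""

    mean: Volume3D
    sd: Volume3D
    count: Volume3D
    mask: MaskVolume

    def __post_init__(self) -> None:
        require_same_grid(self.mean, self.sd, self.count, self.mask)
        if np.any(self.sd.data < -1e-12):
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class VolumeMetrics:
    """Brain volume, ventricle volume, normalised ventricle volume."""

    BV_mL: float
    VV_mL: float

    def __post_init__(self) -> None:
        if not self.BV_mL > 0:
            raise ValueError("brain volume must be positive")

    @property
    def nVV_pct(self) -> float:
        return 100.0 * self.VV_mL / self.BV_mL


def average_images(
    stack: Sequence[Volume3D],
    masks: Sequence[MaskVolume] | None = None,
) -> GroupTemplate:
    """Voxelwise mean and sample SD over a stack of co-registered images.

    Each subject contributes only where its mask is True (all voxels when
    ``masks`` is None).  SD uses the n-1 denominator; voxels with a single
    contribution get SD 0 by convention.  The template mask marks voxels
    with at least one contribution.
    """
    if len(stack) == 0:
        raise ValueError("empty image stack")
    require_same_grid(*stack)
    if masks is not None:
        if len(masks) != len(stack):
            raise ValueError("masks must pair 1:1 with images")
        require_same_grid(stack[0], *masks)
    shape = stack[0].shape
    total = np.zeros(shape)
    count = np.zeros(shape)
    sel = [masks[i].data if masks is not None else np.ones(shape, bool) for i in range(len(stack))]
    for vol, m in zip(stack, sel):
        total += np.where(m, vol.data, 0.0)
        count += m
    mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    # two-pass sample variance avoids catastrophic cancellation
    ssq = np.zeros(shape)
    for vol, m in zip(stack, sel):
        ssq += np.where(m, (vol.data - mean) ** 2, 0.0)
    sd = np.sqrt(ssq / np.maximum(count - 1, 1))
    sd[count < 2] = 0.0
    sp = stack[0].spacing_mm
    return GroupTemplate(
        mean=Volume3D(mean, sp, stack[0].origin_mm),
        sd=Volume3D(sd, sp, stack[0].origin_mm),
        count=Volume3D(count, sp, stack[0].origin_mm),
        mask=MaskVolume(count > 0, sp, stack[0].origin_mm),
    )


def laplacian_sharpen(vol: Volume3D, alpha: float) -> Volume3D:
    """Edge enhancement ``out = in - alpha * L(in)``.

    ``L`` is the 6-neighbour discrete Laplacian (sum of face neighbours minus
    six times the centre) with replicate borders.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    kernel = np.zeros((3, 3, 3))
    kernel[1, 1, 1] = -6.0
    kernel[0, 1, 1] = kernel[2, 1, 1] = 1.0
    kernel[1, 0, 1] = kernel[1, 2, 1] = 1.0
    kernel[1, 1, 0] = kernel[1, 1, 2] = 1.0
    lap = ndimage.convolve(vol.data, kernel, mode="nearest")
    return Volume3D(vol.data - alpha * lap, vol.spacing_mm, vol.origin_mm)


def union_and_thin(
    masks: Sequence[MaskVolume],
    axis: str = "x",
    max_thickness_vox: int = 2,
) -> MaskVolume:
    """Union of membrane masks, thinned along one axis.

    After the union, every 1-D run of foreground voxels along ``axis`` longer
    than ``max_thickness_vox`` keeps only a centred block of
    ``max_thickness_vox`` voxels starting at run offset
    ``floor((L - max_thickness) / 2)``; shorter runs are untouched.  Use
    ``axis="x"`` for the falx (left-right bound) and ``axis="z"`` for the
    tentorium (inferior-superior bound).
    """
    if len(masks) == 0:
        raise ValueError("empty mask list")
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    if max_thickness_vox < 1:
        raise ValueError("max_thickness_vox must be >= 1")
    require_same_grid(*masks)
    union = np.logical_or.reduce([m.data for m in masks])
    a = _AXES[axis]
    moved = np.moveaxis(union, a, -1)
    out = np.zeros_like(moved)
    n = moved.shape[-1]
    flat = moved.reshape(-1, n)
    oflat = out.reshape(-1, n)
    for row in range(flat.shape[0]):
        line = flat[row]
        if not line.any():
            continue
        padded = np.concatenate([[False], line, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            L = e - s
            if L <= max_thickness_vox:
                oflat[row, s:e] = True
            else:
                k = s + (L - max_thickness_vox) // 2
                oflat[row, k : k + max_thickness_vox] = True
    thinned = np.moveaxis(out, -1, a)
    return MaskVolume(thinned, masks[0].spacing_mm, masks[0].origin_mm)


def compute_volumes(
    labels: LabelVolume,
    brain_label_ids: Iterable[int],
    ventricle_label_ids: Iterable[int] = (),
) -> VolumeMetrics:
    """Brain volume (BV), ventricle volume (VV), and nVV = VV/BV x 100.

    BV counts the tissue labels only (ventricular CSF excluded); pass a
    combined set explicitly to change that convention.
    """
    brain_ids = sorted(set(int(i) for i in brain_label_ids) - {0})
    vent_ids = sorted(set(int(i) for i in ventricle_label_ids) - {0})
    vox_ml = labels.voxel_volume_mm3 / 1000.0
    n_brain = int(np.isin(labels.data, brain_ids).sum())
    if n_brain == 0:
        raise ValueError("no brain voxels for the given label ids")
    n_vent = int(np.isin(labels.data, vent_ids).sum()) if vent_ids else 0
    return VolumeMetrics(BV_mL=n_brain * vox_ml, VV_mL=n_vent * vox_ml)
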