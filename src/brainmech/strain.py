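"""Deformation metrics from 4-D displacement fields.

Displacement histories (tagged-MRI style) are differentiated spatially to
build per-frame deformation gradients ``F = I + grad(u)`` and Green-Lagrange
strain tensors ``E = (F^T F - I) / 2`` (finite strain: exactly zero under
rigid motion, unlike the small-strain tensor, which is kept as an option).
Per-voxel scalar metrics follow: MPS, the maximum over the time history of
the largest strain eigenvalue, and MRD, the maximum resultant displacement.
Summaries report median/95th-percentile MPS and MRD plus the volume
fraction of tissue exceeding MPS thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .templates import GroupTemplate
from .volumes import MaskVolume, Volume3D, require_same_grid

__all__ = [
    "DisplacementField",
    "StrainTensorField",
    "DeformationSummary",
    "green_lagrange",
    "mps",
    "mrd",
    "deformation_summary",
    "group_average_strain",
]

# storage order of the six independent tensor components
COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass
class DisplacementField:
    """T x grid x 3 displacement history (mm) with time stamps (ms)."""

    frames: np.ndarray              # (T, nx, ny, nz, 3)
    t_ms: np.ndarray                # (T,)
    spacing_mm: tuple[float, float, float]
    valid: MaskVolume

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        if self.frames.ndim != 5 or self.frames.shape[-1] != 3:
            raise ValueError(f"frames must be (T, nx, ny, nz, 3), got {self.frames.shape}")
        if self.t_ms.shape != (self.frames.shape[0],):
            raise ValueError("t_ms must have one entry per frame")
        if self.t_ms.size > 1 and np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.valid.shape != self.frames.shape[1:4]:
            raise ValueError("valid mask grid does not match the displacement grid")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[1:4]


@dataclass
class StrainTensorField:
    """T x grid x 6 symmetric strain tensor history (order xx,yy,zz,xy,xz,yz)."""

    frames: np.ndarray              # (T, nx, ny, nz, 6)
    spacing_mm: tuple[float, float, float]
    valid: MaskVolume

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 5 or self.frames.shape[-1] != 6:
            raise ValueError(f"frames must be (T, nx, ny, nz, 6), got {self.frames.shape}")

    def tensor(self, frame: int) -> np.ndarray:
        """Full (nx, ny, nz, 3, 3) symmetric tensor of one frame."""
        e = self.frames[frame]
        out = np.empty((*e.shape[:-1], 3, 3))
        out[..., 0, 0] = e[..., 0]
        out[..., 1, 1] = e[..., 1]
        out[..., 2, 2] = e[..., 2]
        out[..., 0, 1] = out[..., 1, 0] = e[..., 3]
        out[..., 0, 2] = out[..., 2, 0] = e[..., 4]
        out[..., 1, 2] = out[..., 2, 1] = e[..., 5]
        return out


@dataclass(frozen=True)
class DeformationSummary:
    """Percentile and volume-fraction deformation metrics."""

    mps_p50: float
    mps_p95: float
    mrd_p50_mm: float
    mrd_p95_mm: float
    vf: Mapping[float, float]       # MPS threshold -> fraction of voxels above

    def __post_init__(self) -> None:
        if self.mps_p50 > self.mps_p95 + 1e-12 or self.mrd_p50_mm > self.mrd_p95_mm + 1e-12:
            raise ValueError("p50 must not exceed p95")


def green_lagrange(disp: DisplacementField, finite: bool = True) -> StrainTensorField:
    """Strain tensor history from a displacement field.

    The displacement gradient uses central differences in physical units
    (one-sided at grid borders).  With ``finite=True`` (default) the
    Green-Lagrange tensor ``E = (F^T F - I)/2`` is returned; with
    ``finite=False`` the small-strain tensor ``(grad u + grad u^T)/2``.
    """
    if min(disp.grid_shape) < 3:
        raise ValueError("grid must be at least 3 voxels per axis")
    T = disp.n_frames
    out = np.empty((T, *disp.grid_shape, 6))
    sp = disp.spacing_mm
    for t in range(T):
        u = disp.frames[t]
        J = np.empty((*disp.grid_shape, 3, 3))
        for i in range(3):
            grads = np.gradient(u[..., i], sp[0], sp[1], sp[2], axis=(0, 1, 2))
            for j in range(3):
                J[..., i, j] = grads[j]
        if finite:
            E = 0.5 * (J + np.swapaxes(J, -1, -2) + np.einsum("...ki,...kj->...ij", J, J))
        else:
            E = 0.5 * (J + np.swapaxes(J, -1, -2))
        out[t, ..., 0] = E[..., 0, 0]
        out[t, ..., 1] = E[..., 1, 1]
        out[t, ..., 2] = E[..., 2, 2]
        out[t, ..., 3] = E[..., 0, 1]
        out[t, ..., 4] = E[..., 0, 2]
        out[t, ..., 5] = E[..., 1, 2]
    return StrainTensorField(frames=out, spacing_mm=sp, valid=disp.valid)


def mps(strain: StrainTensorField) -> Volume3D:
    """Per-voxel peak maximum principal strain over the time history.

    The maximum principal strain of a frame is the largest eigenvalue of the
    symmetric 3x3 strain tensor; the per-voxel output is its maximum over
    frames.
    """
    T = strain.frames.shape[0]
    peak = np.full(strain.frames.shape[1:4], -np.inf)
    for t in range(T):
        tens = strain.tensor(t)
        lam = np.linalg.eigvalsh(tens)[..., -1]
        peak = np.maximum(peak, lam)
    return Volume3D(peak, strain.spacing_mm)


def mrd(disp: DisplacementField) -> Volume3D:
    """Per-voxel maximum resultant displacement (mm) over the time history."""
    norms = np.linalg.norm(disp.frames, axis=-1)
    return Volume3D(norms.max(axis=0), disp.spacing_mm)


def deformation_summary(
    mps_map: Volume3D,
    mrd_map: Volume3D,
    mask: MaskVolume,
    thresholds: Sequence[float] = (0.01, 0.02, 0.03),
) -> DeformationSummary:
    """Percentiles and MPS volume fractions over a tissue mask.

    Percentiles use linear interpolation between order statistics; the
    volume fraction at threshold ``theta`` counts voxels with MPS strictly
    greater than ``theta``.
    """
    require_same_grid(mps_map, mrd_map, mask)
    if not mask.data.any():
        raise ValueError("empty mask")
    ms = mps_map.data[mask.data]
    rs = mrd_map.data[mask.data]
    vf = {float(th): float(np.mean(ms > th)) for th in thresholds}
    return DeformationSummary(
        mps_p50=float(np.percentile(ms, 50.0)),
        mps_p95=float(np.percentile(ms, 95.0)),
        mrd_p50_mm=float(np.percentile(rs, 50.0)),
        mrd_p95_mm=float(np.percentile(rs, 95.0)),
        vf=vf,
    )


def group_average_strain(
    maps: Sequence[Volume3D],
    valids: Sequence[MaskVolume] | None = None,
) -> GroupTemplate:
    """Group-average scalar deformation maps (majority-vote masked).

    Identical contract to :func:`brainmech.mre.group_average_maps` (shared
    implementation): averaging operates on peak-MPS/MRD scalar maps, never
    on tensors, so warping-induced tensor-orientation errors cannot arise.
    """
    from .mre import group_average_maps

    return group_average_maps(maps, valids)
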