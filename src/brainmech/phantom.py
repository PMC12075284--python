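"""Synthetic, pre-aligned head phantoms with known ground truth.

Stands in for a cohort of subjects scanned with structural MRI, MR
elastography and tagged MRI.  Anatomy is a nest of ellipsoids carrying
hemisphere-split tissue labels (merged downstream to the six canonical
regions: cerebrum WM, cortical GM, deep GM, cerebellum WM/GM, brainstem),
lateral ventricles, a dura envelope with a fluid gap, a mid-sagittal falx
sheet and a horizontal tentorium sheet.  Complex shear moduli come from a
known Prony forward model per region; displacement fields are rigid rotation
and/or analytic simple shear so strain is known in closed form.

Cohort conditions mirror the study design the phantom emulates: three age
groups x two sexes, with male brains ~9% larger by volume, a slightly
smaller brain and markedly larger ventricles in the older group, and ~8%
lower shear stiffness in the older group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .prony import PronyMaterial, prony_moduli
from .volumes import LabelVolume, MaskVolume, Volume3D

__all__ = [
    "PhantomSpec",
    "MotionSpec",
    "HeadKinematics",
    "SubjectAnatomy",
    "FINE_LABEL_NAMES",
    "SIX_REGION_MAPPING",
    "REGION_NAMES",
    "VENTRICLE_LABEL",
    "GROUP_MATERIALS",
    "make_anatomy",
    "make_cohort",
    "make_modulus_maps",
    "make_displacement",
    "make_kinematics",
    "analytic_mps",
]

AgeGroup = Literal["young", "midage", "older"]
Sex = Literal["M", "F"]

# Hemisphere-split fine labels (stand-in for a many-label anatomical
# segmentation) and their merge to the six canonical tissue regions.
FINE_LABEL_NAMES: dict[int, str] = {
    11: "cerebrum_wm_left", 12: "cerebrum_wm_right",
    21: "cortical_gm_left", 22: "cortical_gm_right",
    31: "deep_gm_left", 32: "deep_gm_right",
    41: "cerebellum_wm_left", 42: "cerebellum_wm_right",
    51: "cerebellum_gm_left", 52: "cerebellum_gm_right",
    60: "brainstem",
    70: "ventricles",
}

REGION_NAMES: dict[int, str] = {
    1: "cerebrum_wm", 2: "cortical_gm", 3: "deep_gm",
    4: "cerebellum_wm", 5: "cerebellum_gm", 6: "brainstem",
}

VENTRICLE_LABEL = 7

#: fine tissue label -> merged six-region id (ventricles pass through as 7)
SIX_REGION_MAPPING: dict[int, int] = {
    11: 1, 12: 1, 21: 2, 22: 2, 31: 3, 32: 3,
    41: 4, 42: 4, 51: 5, 52: 5, 60: 6, 70: VENTRICLE_LABEL,
}

#: names for the merged label set (six regions + ventricles)
MERGED_LABEL_NAMES: dict[int, str] = {**REGION_NAMES, VENTRICLE_LABEL: "ventricles"}

# Geometry scale factors per age group / sex: older brains slightly smaller
# with much larger ventricles; male brains larger than female.
_AGE_GEOMETRY = {
    "young": {"brain": 1.00, "ventricle": 1.00},
    "midage": {"brain": 0.99, "ventricle": 1.25},
    "older": {"brain": 0.97, "ventricle": 2.00},
}
_SEX_GEOMETRY = {"M": 1.03, "F": 1.00}

# Baseline regional materials (young/mid-age), Pa / seconds.  The older
# group is ~8% softer uniformly, the dominant age effect in elastography.
_BASE_MATERIALS: dict[int, PronyMaterial] = {
    1: PronyMaterial(G0_pa=5200.0, terms=((0.35, 0.05), (0.35, 0.003))),
    2: PronyMaterial(G0_pa=4600.0, terms=((0.35, 0.05), (0.35, 0.003))),
    3: PronyMaterial(G0_pa=4900.0, terms=((0.35, 0.05), (0.35, 0.003))),
    4: PronyMaterial(G0_pa=4200.0, terms=((0.35, 0.05), (0.35, 0.003))),
    5: PronyMaterial(G0_pa=3800.0, terms=((0.35, 0.05), (0.35, 0.003))),
    6: PronyMaterial(G0_pa=4400.0, terms=((0.35, 0.05), (0.35, 0.003))),
}

_AGE_STIFFNESS = {"young": 1.00, "midage": 0.99, "older": 0.92}

#: region id -> PronyMaterial per age group (ground truth of the modulus maps)
GROUP_MATERIALS: dict[str, dict[int, PronyMaterial]] = {
    age: {rid: replace(m, G0_pa=m.G0_pa * s) for rid, m in _BASE_MATERIALS.items()}
    for age, s in _AGE_STIFFNESS.items()
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic head (all lengths mm)."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    brain_radii_mm: tuple[float, float, float] = (54.0, 65.0, 48.0)
    ventricle_radii_mm: tuple[float, float, float] = (9.0, 16.0, 8.0)
    sas_thickness_vox: int = 1
    age_group: AgeGroup = "young"
    sex: Sex = "M"
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(v < r for v, r in zip(self.ventricle_radii_mm, self.brain_radii_mm)):
            raise ValueError("ventricle radii must be smaller than brain radii")
        if self.sas_thickness_vox < 1:
            raise ValueError("sas_thickness_vox must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.age_group not in _AGE_GEOMETRY:
            raise ValueError(f"unknown age group {self.age_group!r}")
        if self.sex not in _SEX_GEOMETRY:
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass(frozen=True)
class MotionSpec:
    """Prescribed bulk motion for the displacement generator."""

    kind: Literal["rigid_rotation", "simple_shear", "composite"] = "rigid_rotation"
    angle_rad: float = 0.05
    gamma: float = 0.1
    axis: Literal["x", "y", "z"] = "z"
    n_frames: int = 5
    frame_dt_ms: float = 18.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.frame_dt_ms > 0:
            raise ValueError("frame_dt_ms must be positive")
        if self.kind not in ("rigid_rotation", "simple_shear", "composite"):
            raise ValueError(f"unknown motion kind {self.kind!r}")


@dataclass
class HeadKinematics:
    """Angular velocity/acceleration time series of a head rotation."""

    t_ms: np.ndarray
    omega_rad_s: np.ndarray
    alpha_rad_s2: np.ndarray
    axis: Literal["x", "y", "z"] = "z"
    pivot_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.omega_rad_s = np.asarray(self.omega_rad_s, dtype=float)
        self.alpha_rad_s2 = np.asarray(self.alpha_rad_s2, dtype=float)
        if np.any(np.diff(self.t_ms) <= 0):
            raise ValueError("time samples must be strictly increasing")

    @property
    def omega_peak(self) -> float:
        return float(np.max(np.abs(self.omega_rad_s)))

    @property
    def alpha_peak(self) -> float:
        return float(np.max(np.abs(self.alpha_rad_s2)))

    @property
    def duration_ms(self) -> float:
        return float(self.t_ms[-1] - self.t_ms[0])

    def consistent(self, rel_tol: float = 0.05) -> bool:
        """True when alpha matches the numeric derivative of omega."""
        num = np.gradient(self.omega_rad_s, self.t_ms * 1e-3)
        scale = max(self.alpha_peak, 1e-12)
        # numeric differentiation is worst at the ends; compare interior
        return bool(np.max(np.abs(num - self.alpha_rad_s2)[1:-1]) <= rel_tol * scale)


@dataclass
class SubjectAnatomy:
    """One phantom subject's pre-aligned volumes."""

    labels: LabelVolume          # hemisphere-split fine labels + ventricles
    dura: MaskVolume             # envelope: brain + fluid gap
    falx: MaskVolume
    tentorium: MaskVolume
    t1_like: Volume3D
    t2_like: Volume3D
    spec: PhantomSpec


def _ellipsoid(coords, center, radii) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def make_anatomy(spec: PhantomSpec) -> SubjectAnatomy:
    """Build one phantom subject from ``spec`` (deterministic given the seed)."""
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing_mm)
    extent = shape * spacing
    rng = np.random.default_rng(spec.seed)

    geo = _AGE_GEOMETRY[spec.age_group]
    bscale = geo["brain"] * _SEX_GEOMETRY[spec.sex]
    brain_r = np.asarray(spec.brain_radii_mm) * bscale
    vent_r = np.asarray(spec.ventricle_radii_mm) * geo["ventricle"] ** (1 / 3) * bscale
    if spec.jitter_sd > 0:
        brain_r = brain_r * (1.0 + rng.normal(0.0, spec.jitter_sd, 3))
        vent_r = vent_r * (1.0 + rng.normal(0.0, spec.jitter_sd, 3))
    if np.any(vent_r >= brain_r):
        raise ValueError("ventricle radii must stay smaller than brain radii")
    idx = np.indices(shape, dtype=float)
    coords = [idx[a] * spacing[a] for a in range(3)]
    cx, cy, cz = extent / 2.0
    # lift the brain so the brainstem stump and its dural/skull floor fit below
    z_floor_vox = spec.sas_thickness_vox + 1
    center = np.array([cx, cy, cz + 0.06 * extent[2]])

    margin = (spec.sas_thickness_vox + 2) * spacing
    if np.any(center - brain_r < margin) or np.any(center + brain_r > extent - margin):
        raise ValueError(
            f"brain radii {tuple(brain_r)} exceed the grid extent {tuple(extent)}"
        )

    x, y, z = coords
    labels = np.zeros(shape, dtype=np.int32)

    # tentorium plane separates cerebrum (above) from cerebellum (below)
    z_tent = center[2] - 0.45 * brain_r[2]

    cerebrum = _ellipsoid(coords, center, brain_r) & (z > z_tent + spacing[2])
    rnorm = np.sqrt(
        ((x - center[0]) / brain_r[0]) ** 2
        + ((y - center[1]) / brain_r[1]) ** 2
        + ((z - center[2]) / brain_r[2]) ** 2
    )
    falx_slot = np.abs(x - cx) < 0.6 * spacing[0]  # interhemispheric gap
    gap_region = falx_slot & (z > center[2])
    cerebrum &= ~gap_region
    left = x < cx

    cort = cerebrum & (rnorm > 0.82)
    cwm = cerebrum & (rnorm <= 0.82)
    labels[cwm & left] = 11
    labels[cwm & ~left] = 12
    labels[cort & left] = 21
    labels[cort & ~left] = 22

    deep_c = center + np.array([0.0, 0.0, -0.15 * brain_r[2]])
    deep = _ellipsoid(coords, deep_c, 0.30 * brain_r) & cerebrum
    labels[deep & left] = 31
    labels[deep & ~left] = 32

    # cerebellum: posterior-inferior ellipsoid below the tentorium
    cb_center = np.array([cx, center[1] - 0.45 * brain_r[1], z_tent - 0.35 * brain_r[2]])
    cb_r = np.array([0.50 * brain_r[0], 0.38 * brain_r[1], 0.30 * brain_r[2]])
    cereb = _ellipsoid(coords, cb_center, cb_r) & (z < z_tent - spacing[2])
    cb_rnorm = np.sqrt(
        ((x - cb_center[0]) / cb_r[0]) ** 2
        + ((y - cb_center[1]) / cb_r[1]) ** 2
        + ((z - cb_center[2]) / cb_r[2]) ** 2
    )
    labels[cereb & (cb_rnorm <= 0.7) & left] = 41
    labels[cereb & (cb_rnorm <= 0.7) & ~left] = 42
    labels[cereb & (cb_rnorm > 0.7) & left] = 51
    labels[cereb & (cb_rnorm > 0.7) & ~left] = 52

    # brainstem: anterior cylinder descending to within 2 voxels of the floor
    bs_r = max(3.0 * float(spacing.min()), 0.14 * brain_r[0])
    bs_xy = np.sqrt((x - cx) ** 2 + (y - (center[1] + 0.18 * brain_r[1])) ** 2) <= bs_r
    z_bot = z_floor_vox * spacing[2]
    stem = bs_xy & (z >= z_bot - 0.5 * spacing[2]) & (z <= z_tent + 2 * spacing[2])
    labels[stem] = 60

    vent_c = center + np.array([0.0, 0.1 * brain_r[1], 0.05 * brain_r[2]])
    vent = _ellipsoid(coords, vent_c, vent_r)
    labels[vent] = 70

    brainish = labels > 0

    falx = gap_region & (rnorm <= 0.95) & (z > center[2] + 0.05 * brain_r[2])
    tent_slab = (np.abs(z - z_tent) <= 0.5 * spacing[2]) & (y < center[1])
    tent = (
        tent_slab
        & _ellipsoid(coords, center, brain_r * np.array([1.0, 1.0, 1.6]))
        & ~bs_xy
        & ~brainish
    )

    dura = ndimage.binary_dilation(
        brainish | falx | tent, structure=_STRUCT6, iterations=spec.sas_thickness_vox
    )

    # piecewise-constant intensities plus a smooth multiplicative bias field
    t1_means = {0: 30.0, 11: 110.0, 12: 110.0, 21: 80.0, 22: 80.0, 31: 95.0, 32: 95.0,
                41: 105.0, 42: 105.0, 51: 85.0, 52: 85.0, 60: 100.0, 70: 35.0}
    t2_means = {0: 20.0, 11: 70.0, 12: 70.0, 21: 95.0, 22: 95.0, 31: 85.0, 32: 85.0,
                41: 72.0, 42: 72.0, 51: 92.0, 52: 92.0, 60: 78.0, 70: 160.0}
    lut1 = np.zeros(max(t1_means) + 1)
    lut2 = np.zeros(max(t2_means) + 1)
    for k, v in t1_means.items():
        lut1[k] = v
    for k, v in t2_means.items():
        lut2[k] = v
    bias = 1.0 + 0.05 * np.sin(np.pi * x / extent[0]) * np.sin(np.pi * y / extent[1])
    t1 = lut1[labels] * bias
    t2 = lut2[labels] * bias

    for fid in FINE_LABEL_NAMES:
        if not (labels == fid).any():
            raise RuntimeError(f"phantom construction lost label {fid} ({FINE_LABEL_NAMES[fid]})")

    sp = tuple(float(s) for s in spec.spacing_mm)
    return SubjectAnatomy(
        labels=LabelVolume(labels, sp, dict(FINE_LABEL_NAMES)),
        dura=MaskVolume(dura, sp),
        falx=MaskVolume(falx, sp),
        tentorium=MaskVolume(tent, sp),
        t1_like=Volume3D(t1, sp),
        t2_like=Volume3D(t2, sp),
        spec=spec,
    )


def subject_seed(master_seed: int, subject_index: int) -> int:
    """Deterministic per-subject seed derived from the master seed."""
    return int(np.random.SeedSequence([master_seed, subject_index]).generate_state(1)[0] % (2**31))


def make_cohort(spec: PhantomSpec, n_subjects: int) -> list[SubjectAnatomy]:
    """Generate ``n_subjects`` phantoms on one shared grid.

    Per-subject geometric jitter is controlled by ``spec.jitter_sd``; subject
    seeds derive deterministically from ``spec.seed`` and the subject index.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return [
        make_anatomy(replace(spec, seed=subject_seed(spec.seed, i)))
        for i in range(n_subjects)
    ]


def make_modulus_maps(
    labels: LabelVolume,
    region_materials: Mapping[int, PronyMaterial],
    freqs_hz: Sequence[float] = (30.0, 50.0, 70.0),
    noise_sd_frac: float = 0.0,
    seed: int = 0,
    label_to_region: Mapping[int, int] | None = None,
):
    """Forward-model complex shear modulus maps from regional Prony materials.

    Per voxel, ``(G', G'')`` is the Prony forward model of its region's
    material at each frequency, times independent multiplicative Gaussian
    noise ``(1 + N(0, noise_sd_frac))``.  The valid mask covers exactly the
    voxels whose (merged) region has a material.  ``label_to_region`` maps
    fine labels to the material keys (defaults to :data:`SIX_REGION_MAPPING`
    restricted to labels present).

    Returns a list of :class:`~brainmech.mre.ComplexModulusMap`, one per
    frequency.
    """
    from .mre import ComplexModulusMap  # local import to avoid a cycle

    if any(f <= 0 for f in freqs_hz):
        raise ValueError("frequencies must be positive")
    mapping = dict(label_to_region) if label_to_region is not None else dict(SIX_REGION_MAPPING)
    rng = np.random.default_rng(seed)
    present = [int(v) for v in np.unique(labels.data) if v != 0]
    region_of: dict[int, int] = {}
    for lab in present:
        reg = mapping.get(lab, lab)
        if reg in region_materials:
            region_of[lab] = reg
        elif lab in region_materials:
            region_of[lab] = lab
    tissue_like = [lab for lab in present if mapping.get(lab, lab) in REGION_NAMES or lab in REGION_NAMES]
    missing = [lab for lab in tissue_like if lab not in region_of]
    if missing:
        raise ValueError(f"no material for tissue labels {missing}")

    valid = np.isin(labels.data, list(region_of))
    out = []
    for f in freqs_hz:
        gp = np.zeros(labels.shape)
        gpp = np.zeros(labels.shape)
        for lab, reg in region_of.items():
            p, pp = prony_moduli(region_materials[reg], f)
            sel = labels.data == lab
            gp[sel] = p
            gpp[sel] = pp
        if noise_sd_frac > 0:
            gp = gp * (1.0 + rng.normal(0.0, noise_sd_frac, gp.shape))
            gpp = gpp * (1.0 + rng.normal(0.0, noise_sd_frac, gpp.shape))
        gp[valid] = np.maximum(gp[valid], 1e-6)
        gpp[valid] = np.maximum(gpp[valid], 0.0)
        out.append(
            ComplexModulusMap(
                frequency_hz=float(f),
                storage=Volume3D(gp, labels.spacing_mm),
                loss=Volume3D(gpp, labels.spacing_mm),
                valid=MaskVolume(valid, labels.spacing_mm),
            )
        )
    return out


_AXES = {"x": 0, "y": 1, "z": 2}


def _rotation_matrix(axis: str, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    if axis == "z":
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    if axis == "y":
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def make_displacement(labels: LabelVolume, motion: MotionSpec):
    """Analytic 4-D displacement field for a phantom.

    ``rigid_rotation``: ``u(x) = (R(theta_t) - I)(x - pivot)`` about the grid
    centre, with the angle ramping linearly to ``angle_rad`` at the last
    frame.  ``simple_shear``: ``u_x = gamma_t * (y - y_c)``, other components
    zero.  ``composite`` sums both.  Ground-truth strain is known in closed
    form for every mode (see :func:`analytic_mps`).
    """
    from .strain import DisplacementField  # local import to avoid a cycle

    shape = labels.shape
    spacing = np.asarray(labels.spacing_mm)
    idx = np.indices(shape, dtype=float)
    coords = np.stack([idx[a] * spacing[a] for a in range(3)], axis=-1)
    pivot = (np.asarray(shape) - 1) * spacing / 2.0
    rel = coords - pivot

    T = motion.n_frames
    scales = np.arange(1, T + 1) / T
    frames = np.zeros((T, *shape, 3))
    for t, s in enumerate(scales):
        u = np.zeros((*shape, 3))
        if motion.kind in ("rigid_rotation", "composite"):
            R = _rotation_matrix(motion.axis, s * motion.angle_rad)
            u = u + rel @ (R - np.eye(3)).T
        if motion.kind in ("simple_shear", "composite"):
            u[..., 0] = u[..., 0] + s * motion.gamma * rel[..., 1]
        frames[t] = u
    t_ms = scales * T * motion.frame_dt_ms
    return DisplacementField(
        frames=frames,
        t_ms=t_ms,
        spacing_mm=tuple(float(s) for s in spacing),
        valid=MaskVolume(labels.data > 0, labels.spacing_mm),
    )


def analytic_mps(motion: MotionSpec) -> float:
    """Ground-truth peak maximum principal strain for a MotionSpec.

    Both motion modes are spatially linear, so the deformation gradient is
    uniform: ``F = R(angle)`` for rigid rotation (zero Green-Lagrange
    strain), ``F = I + gamma e_x (x) e_y`` for simple shear, and their sum
    minus the identity for composite motion.  Simple shear has
    ``E = [[0, g/2, 0], [g/2, g^2/2, 0], [0, 0, 0]]`` with largest
    eigenvalue ``(g^2/2 + g*sqrt(g^2+4)/2) / 2``; the general case takes
    the largest eigenvalue of ``(F^T F - I)/2`` for the uniform ``F``.
    """
    if motion.kind == "rigid_rotation":
        return 0.0
    if motion.kind == "simple_shear":
        g = motion.gamma
        return (g * g / 2.0 + g * math.sqrt(g * g + 4.0) / 2.0) / 2.0
    F = _rotation_matrix(motion.axis, motion.angle_rad)
    F = F + motion.gamma * np.outer([1.0, 0.0, 0.0], [0.0, 1.0, 0.0])
    E = 0.5 * (F.T @ F - np.eye(3))
    return float(np.linalg.eigvalsh(E)[-1])


def make_kinematics(
    omega_peak_rad_s: float,
    duration_ms: float,
    axis: Literal["x", "y", "z"] = "z",
    pivot_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    n_samples: int = 201,
) -> HeadKinematics:
    """Half-sine angular-velocity pulse with the stated peak.

    ``omega(t) = omega_peak * sin(pi t / T)`` over ``t in [0, T]``; the
    analytic derivative gives ``alpha_peak = omega_peak * pi / T`` and a net
    rotation angle of ``omega_peak * 2T / pi``.
    """
    if not omega_peak_rad_s > 0:
        raise ValueError("omega_peak must be positive")
    if not duration_ms > 0:
        raise ValueError("duration must be positive")
    t_ms = np.linspace(0.0, duration_ms, n_samples)
    T_s = duration_ms * 1e-3
    omega = omega_peak_rad_s * np.sin(np.pi * t_ms * 1e-3 / T_s)
    alpha = omega_peak_rad_s * np.pi / T_s * np.cos(np.pi * t_ms * 1e-3 / T_s)
    return HeadKinematics(t_ms=t_ms, omega_rad_s=omega, alpha_rad_s2=alpha,
                          axis=axis, pivot_mm=pivot_mm)
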