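"""Voxel-based 11-part hexahedral finite-element head model.

The refined segmentation augments the six merged brain regions and the
ventricles with a subarachnoid-space (SAS) layer, a skull shell, a
falx/tentorium membrane part and a foramen opening at the brainstem:

1. SAS = inside the dura envelope, outside brain/ventricles/falx+tentorium;
2. skull = a one-voxel 6-connected shell immediately outside the dura;
3. separation repair guarantees no brain voxel touches a skull voxel
   face-on (offending skull voxels become SAS and the shell re-closes
   outward);
4. falx columns are extended superiorly through the SAS until they meet
   the skull;
5. below the lowest brainstem slice, within that slice's axial footprint,
   SAS voxels become brainstem and skull voxels become foramen, keeping
   the spinal-cord path open.

Each occupied voxel becomes one constant-stress 8-node hexahedral element
on a shared corner-node lattice; the deck is exported in LS-Dyna keyword
format (g-mm-ms unit system, stresses in MPa) with viscoelastic material
cards, a rigid skull and its prescribed rotational motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import HeadKinematics
from .prony import PronyMaterial, SAS_MATERIAL
from .volumes import LabelVolume, MaskVolume

__all__ = [
    "PART_IDS",
    "PART_NAMES",
    "RefinedSegmentation",
    "HexMesh",
    "MaterialCard",
    "DEFAULT_FIXED_MATERIALS",
    "refine_segmentation",
    "build_hex_mesh",
    "assign_materials",
    "export_keyword",
    "read_keyword",
    "mesh_report",
]

log = logging.getLogger(__name__)

#: the 11 model parts (six brain regions keep their region ids 1-6)
PART_IDS = {
    "cerebrum_wm": 1, "cortical_gm": 2, "deep_gm": 3,
    "cerebellum_wm": 4, "cerebellum_gm": 5, "brainstem": 6,
    "ventricles": 7, "sas": 8, "falx_tentorium": 9, "foramen": 10, "skull": 11,
}
PART_NAMES = {v: k for k, v in PART_IDS.items()}

_BRAIN_PARTS = (1, 2, 3, 4, 5, 6)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class RefinedSegmentation:
    """11-part label volume ready for meshing."""

    labels: LabelVolume

    def __post_init__(self) -> None:
        present = set(int(v) for v in np.unique(self.labels.data)) - {0}
        unknown = present - set(PART_NAMES)
        if unknown:
            raise ValueError(f"unknown part ids {sorted(unknown)}")

    @property
    def part_ids_present(self) -> list[int]:
        return sorted(set(int(v) for v in np.unique(self.labels.data)) - {0})


@dataclass
class HexMesh:
    """Shared-node hexahedral mesh with per-element part ids."""

    node_ids: np.ndarray        # (n_nodes,) int64, 1-based, strictly increasing
    node_xyz: np.ndarray        # (n_nodes, 3) float64, mm
    elem_ids: np.ndarray        # (n_elems,) int64, 1-based
    conn: np.ndarray            # (n_elems, 8) int64 node ids, brick corner order
    part_ids: np.ndarray        # (n_elems,) int32
    part_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(np.unique(self.node_ids)) != len(self.node_ids):
            raise ValueError("duplicate node ids")
        if len(np.unique(self.elem_ids)) != len(self.elem_ids):
            raise ValueError("duplicate element ids")
        if self.conn.shape != (len(self.elem_ids), 8):
            raise ValueError("connectivity must be (n_elems, 8)")
        if np.any(np.sort(self.conn, axis=1)[:, :-1] == np.sort(self.conn, axis=1)[:, 1:]):
            raise ValueError("element with repeated nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_elements(self) -> int:
        return len(self.elem_ids)

    def element_volumes(self) -> np.ndarray:
        """Signed parallelepiped volume of each (voxel-shaped) hexahedron."""
        pos = {nid: i for i, nid in enumerate(self.node_ids)}
        xyz = self.node_xyz[np.vectorize(pos.get)(self.conn)]
        e1 = xyz[:, 1] - xyz[:, 0]
        e2 = xyz[:, 3] - xyz[:, 0]
        e3 = xyz[:, 4] - xyz[:, 0]
        return np.einsum("ij,ij->i", np.cross(e1, e2), e3)


@dataclass(frozen=True)
class MaterialCard:
    """Solver material assignment for one part."""

    part_id: int
    model: Literal["prony_viscoelastic", "rigid"]
    material: PronyMaterial | None = None          # viscoelastic parts
    rho_g_cm3: float | None = None                 # rigid parts
    E_pa: float | None = None
    nu: float | None = None

    def __post_init__(self) -> None:
        if self.model == "prony_viscoelastic" and self.material is None:
            raise ValueError("viscoelastic card needs a PronyMaterial")
        if self.model == "rigid" and None in (self.rho_g_cm3, self.E_pa, self.nu):
            raise ValueError("rigid card needs rho, E, nu")


#: Placeholder cards for parts whose properties the pipeline does not fit
#: from elastography (membranes, CSF spaces, skull).  Values are plausible
#: defaults in the range used by voxel head models and are meant to be
#: overridden by the user's own configuration.
DEFAULT_FIXED_MATERIALS: dict[str, MaterialCard] = {
    "sas": MaterialCard(PART_IDS["sas"], "prony_viscoelastic", material=SAS_MATERIAL),
    "ventricles": MaterialCard(
        PART_IDS["ventricles"], "prony_viscoelastic",
        material=PronyMaterial(G0_pa=500.0, terms=((0.8, 0.0125),), rho_g_cm3=1.04, K_pa=2.19e9),
    ),
    "foramen": MaterialCard(
        PART_IDS["foramen"], "prony_viscoelastic",
        material=PronyMaterial(G0_pa=500.0, terms=((0.8, 0.0125),), rho_g_cm3=1.04, K_pa=2.19e9),
    ),
    "falx_tentorium": MaterialCard(
        PART_IDS["falx_tentorium"], "prony_viscoelastic",
        material=PronyMaterial(G0_pa=1.15e7, terms=(), rho_g_cm3=1.13, K_pa=2.19e9),
    ),
    "skull": MaterialCard(PART_IDS["skull"], "rigid", rho_g_cm3=1.80, E_pa=6.5e9, nu=0.21),
}


def _dilate(mask: np.ndarray) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=_STRUCT6)


def _separation_repair(out: np.ndarray, max_iters: int) -> None:
    """Relabel skull voxels touching brain face-on as SAS, re-closing the
    shell outward by one voxel locally, until no adjacency remains."""
    for _ in range(max_iters):
        bad = (out == PART_IDS["skull"]) & _dilate(np.isin(out, _BRAIN_PARTS))
        if not bad.any():
            return
        out[bad] = PART_IDS["sas"]
        regrow = _dilate(bad) & (out == 0)
        out[regrow] = PART_IDS["skull"]
    raise RuntimeError("SAS separation repair did not converge")


def refine_segmentation(
    tissue: LabelVolume,
    ventricles: MaskVolume,
    dura: MaskVolume,
    falx_tent: MaskVolume,
    max_repair_iters: int = 10,
) -> RefinedSegmentation:
    """Build the 11-part segmentation from merged tissue labels and masks.

    ``tissue`` must carry the six region ids 1-6 (use
    :func:`brainmech.mre.merge_regions` first); ventricle voxels may be
    encoded either in ``tissue`` as label 7 or via ``ventricles``.
    """
    data = tissue.data
    brain = np.isin(data, _BRAIN_PARTS)
    vent = ventricles.data | (data == PART_IDS["ventricles"])
    if not (data == PART_IDS["brainstem"]).any():
        raise ValueError("brainstem label missing from the tissue segmentation")
    if np.any(brain & ~dura.data):
        raise ValueError("brain voxels outside the dura envelope")

    out = np.zeros(data.shape, dtype=np.int32)
    for rid in _BRAIN_PARTS:
        out[data == rid] = rid
    out[vent] = PART_IDS["ventricles"]
    membrane = falx_tent.data & (out == 0)
    out[membrane] = PART_IDS["falx_tentorium"]
    sas = dura.data & (out == 0)
    out[sas] = PART_IDS["sas"]
    skull = _dilate(dura.data) & ~dura.data & (out == 0)
    out[skull] = PART_IDS["skull"]

    _separation_repair(out, max_repair_iters)

    # falx/tentorium: extend each membrane column superiorly to the skull
    mem = out == PART_IDS["falx_tentorium"]
    cols = np.argwhere(mem.any(axis=2))
    nz = out.shape[2]
    unconnected = 0
    for ix, iy in cols:
        top = int(np.max(np.nonzero(mem[ix, iy])[0]))
        z = top + 1
        reached = False
        while z < nz:
            part = out[ix, iy, z]
            if part == PART_IDS["skull"]:
                reached = True
                break
            if part == PART_IDS["sas"]:
                out[ix, iy, z] = PART_IDS["falx_tentorium"]
                z += 1
                continue
            break  # brain/ventricle/background above: leave unextended
        if not reached:
            unconnected += 1
    if unconnected:
        log.info("falx/tentorium: %d columns did not reach the skull", unconnected)

    # foramen: open the skull floor under the brainstem
    stem = out == PART_IDS["brainstem"]
    z_b = int(np.min(np.nonzero(stem.any(axis=(0, 1)))[0]))
    footprint = stem[:, :, z_b]
    for z in range(z_b):
        sl = out[:, :, z]
        sl[footprint & (sl == PART_IDS["sas"])] = PART_IDS["brainstem"]
        sl[footprint & (sl == PART_IDS["skull"])] = PART_IDS["foramen"]

    # relabeled brainstem voxels below z_b can touch the lateral skull ring;
    # a final repair pass restores the adjacency-free postcondition
    _separation_repair(out, max_repair_iters)

    return RefinedSegmentation(
        LabelVolume(out, tissue.spacing_mm, dict(PART_NAMES), tissue.origin_mm)
    )


# brick corner offsets: counterclockwise bottom face (+z up), then top face
_CORNERS = np.array(
    [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
     (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)], dtype=np.int64
)


def build_hex_mesh(seg: RefinedSegmentation) -> HexMesh:
    """One hexahedral element per non-background voxel, shared corner nodes.

    Node ids are assigned row-major over the ``(nx+1, ny+1, nz+1)`` corner
    lattice (x fastest), so shared faces automatically share nodes; the
    right-handed corner ordering makes every element volume equal the
    (positive) voxel volume.
    """
    lab = seg.labels
    occ = lab.data > 0
    if not occ.any():
        raise ValueError("empty segmentation")
    nx, ny, nz = lab.shape
    vi = np.argwhere(occ)                       # (ne, 3)
    corners = vi[:, None, :] + _CORNERS[None]   # (ne, 8, 3)
    nid = 1 + corners[..., 0] + (nx + 1) * (corners[..., 1] + (ny + 1) * corners[..., 2])
    unique_ids = np.unique(nid)
    ci = (unique_ids - 1) % (nx + 1)
    rem = (unique_ids - 1) // (nx + 1)
    cj = rem % (ny + 1)
    ck = rem // (ny + 1)
    sp = np.asarray(lab.spacing_mm)
    org = np.asarray(lab.origin_mm)
    xyz = org + np.stack([ci, cj, ck], axis=1) * sp
    return HexMesh(
        node_ids=unique_ids.astype(np.int64),
        node_xyz=xyz.astype(float),
        elem_ids=np.arange(1, len(vi) + 1, dtype=np.int64),
        conn=nid.astype(np.int64),
        part_ids=lab.data[occ.nonzero()].astype(np.int32),
        part_names=dict(PART_NAMES),
    )


def assign_materials(
    mesh: HexMesh,
    region_mats: Mapping[int, PronyMaterial],
    fixed_mats: Mapping[str, MaterialCard] | None = None,
) -> list[MaterialCard]:
    """One material card per part present in the mesh.

    Brain parts (1-6) take the fitted regional Prony materials; the SAS gets
    its standard card (rho=1.04 g/cm^3, K=2.19 GPa, G0=0.5 kPa, g1=0.8,
    tau1=12.5 ms); skull is rigid; membranes/ventricles/foramen come from
    ``fixed_mats`` (defaults shipped, user-overridable).
    """
    fixed = dict(DEFAULT_FIXED_MATERIALS)
    if fixed_mats:
        fixed.update(fixed_mats)
    cards: list[MaterialCard] = []
    for pid in sorted(set(int(p) for p in np.unique(mesh.part_ids))):
        name = PART_NAMES.get(pid, str(pid))
        if pid in _BRAIN_PARTS:
            if pid not in region_mats:
                raise ValueError(f"no fitted material for brain part {pid} ({name})")
            cards.append(MaterialCard(pid, "prony_viscoelastic", material=region_mats[pid]))
        elif name in fixed:
            card = fixed[name]
            if card.part_id != pid:
                card = MaterialCard(pid, card.model, card.material, card.rho_g_cm3, card.E_pa, card.nu)
            cards.append(card)
        else:
            raise ValueError(f"no material card resolvable for part {pid} ({name})")
    return cards


# ---------------------------------------------------------------- keyword I/O
# Unit system g-mm-ms: stress in MPa (1 g/(mm*ms^2) = 1 MPa), density in
# g/mm^3, time in ms, angular velocity in rad/ms.

_DOF_ROT = {"x": 5, "y": 6, "z": 7}


def _mat_cards_text(card: MaterialCard) -> str:
    pid = card.part_id
    if card.model == "rigid":
        ro = card.rho_g_cm3 * 1e-3
        e = card.E_pa * 1e-6
        return (
            "*MAT_RIGID\n"
            f"{pid:10d}{ro:10.3E}{e:10.3E}{card.nu:10.4f}\n"
            f"{0.0:10.1f}{0.0:10.1f}{0.0:10.1f}\n"
            f"{0.0:10.1f}{0.0:10.1f}{0.0:10.1f}\n"
        )
    m = card.material
    ro = m.rho_g_cm3 * 1e-3
    bulk = m.K_pa * 1e-6
    lines = [
        "*MAT_GENERAL_VISCOELASTIC",
        f"{pid:10d}{ro:10.3E}{bulk:10.3E}{0.0:10.1f}{0.0:10.1f}{0.0:10.1f}",
    ]
    # shear relaxation as exponential series: long-term term (beta = 0) + Prony terms
    pairs = [(m.Ginf_pa * 1e-6, 0.0)] if m.Ginf_pa > 0 else []
    pairs += [(m.G0_pa * g * 1e-6, 1.0 / (tau * 1e3)) for g, tau in m.terms]
    for gi, beta in pairs:
        lines.append(f"{gi:10.3E}{beta:10.3E}")
    return "\n".join(lines) + "\n"


def export_keyword(
    mesh: HexMesh,
    cards: Sequence[MaterialCard],
    kin: HeadKinematics,
    path,
    termination_ms: float = 160.0,
) -> Path:
    """Write an LS-Dyna ASCII keyword deck for the head model.

    The deck contains *NODE (I8 ids, E16.9 coordinates), *ELEMENT_SOLID,
    one *PART per part with a constant-stress solid section, viscoelastic
    and rigid *MAT_* cards, a *DEFINE_CURVE of angular velocity vs time and
    prescribed rotational motion of the rigid skull about the kinematics
    axis through its pivot.  Node/element records round-trip bit-exactly
    through :func:`read_keyword`.
    """
    if kin.t_ms[-1] < termination_ms:
        raise ValueError(
            f"kinematics end at {kin.t_ms[-1]} ms, before termination at {termination_ms} ms"
        )
    by_pid = {c.part_id: c for c in cards}
    present = sorted(set(int(p) for p in np.unique(mesh.part_ids)))
    missing = [p for p in present if p not in by_pid]
    if missing:
        raise ValueError(f"no material card for parts {missing}")

    path = Path(path)
    out = []
    out.append("*KEYWORD\n*TITLE\ngroup-average voxel head model (unit system g-mm-ms)\n")
    out.append(f"*CONTROL_TERMINATION\n{termination_ms:10.4f}\n")
    out.append("*SECTION_SOLID\n" + f"{1:10d}{1:10d}\n")  # ELFORM 1: constant stress
    for pid in present:
        out.append(_mat_cards_text(by_pid[pid]))
    for pid in present:
        name = mesh.part_names.get(pid, f"part_{pid}")
        out.append("*PART\n" + f"{name}\n" + f"{pid:10d}{1:10d}{pid:10d}\n")
    node_lines = ["*NODE\n"]
    for nid, (xc, yc, zc) in zip(mesh.node_ids, mesh.node_xyz):
        node_lines.append(f"{nid:8d}{xc:16.9E}{yc:16.9E}{zc:16.9E}\n")
    out.append("".join(node_lines))
    el_lines = ["*ELEMENT_SOLID\n"]
    for eid, pid, cn in zip(mesh.elem_ids, mesh.part_ids, mesh.conn):
        el_lines.append(f"{eid:8d}{pid:8d}" + "".join(f"{n:8d}" for n in cn) + "\n")
    out.append("".join(el_lines))
    out.append("*DEFINE_CURVE\n" + f"{1:10d}\n")
    for t, w in zip(kin.t_ms, kin.omega_rad_s):
        out.append(f"{t:20.10E}{w * 1e-3:20.10E}\n")   # ms, rad/ms
    px, py, pz = kin.pivot_mm
    out.append(
        "*DEFINE_COORDINATE_SYSTEM\n"
        f"{1:10d}{px:10.3f}{py:10.3f}{pz:10.3f}\n"
    )
    skull_pid = PART_IDS["skull"]
    if skull_pid in present:
        dof = _DOF_ROT[kin.axis]
        out.append(
            "*BOUNDARY_PRESCRIBED_MOTION_RIGID\n"
            f"{skull_pid:10d}{dof:10d}{0:10d}{1:10d}{1.0:10.4f}\n"
        )
    out.append("*END\n")
    path.write_text("".join(out))
    return path


def read_keyword(path) -> HexMesh:
    """Parse *NODE / *ELEMENT_SOLID / *PART from a keyword deck.

    Companion reader for :func:`export_keyword` round trips; it recovers
    nodes, connectivity and part assignment (not materials or loading).
    """
    nodes: list[tuple[int, float, float, float]] = []
    elems: list[tuple[int, int, list[int]]] = []
    part_names: dict[int, str] = {}
    section = None
    pending_name: str | None = None
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("$"):
            continue
        if raw.startswith("*"):
            section = raw.strip().upper()
            pending_name = None
            continue
        if section == "*NODE":
            nodes.append((int(raw[:8]), float(raw[8:24]), float(raw[24:40]), float(raw[40:56])))
        elif section == "*ELEMENT_SOLID":
            eid = int(raw[:8])
            pid = int(raw[8:16])
            conn = [int(raw[16 + 8 * i : 24 + 8 * i]) for i in range(8)]
            elems.append((eid, pid, conn))
        elif section == "*PART":
            if pending_name is None:
                pending_name = raw.strip()
            else:
                part_names[int(raw[:10])] = pending_name
                pending_name = None
    if not nodes or not elems:
        raise ValueError(f"{path}: no nodes/elements found")
    nid = np.array([n[0] for n in nodes], dtype=np.int64)
    order = np.argsort(nid)
    xyz = np.array([(n[1], n[2], n[3]) for n in nodes])[order]
    return HexMesh(
        node_ids=nid[order],
        node_xyz=xyz,
        elem_ids=np.array([e[0] for e in elems], dtype=np.int64),
        conn=np.array([e[2] for e in elems], dtype=np.int64),
        part_ids=np.array([e[1] for e in elems], dtype=np.int32),
        part_names=part_names,
    )


def _brain_skull_adjacencies(seg_data: np.ndarray) -> int:
    brain = np.isin(seg_data, _BRAIN_PARTS)
    skull = seg_data == PART_IDS["skull"]
    n = 0
    for axis in range(3):
        a = np.take(brain, range(0, brain.shape[axis] - 1), axis=axis)
        b = np.take(skull, range(1, skull.shape[axis]), axis=axis)
        n += int(np.sum(a & b))
        a = np.take(skull, range(0, skull.shape[axis] - 1), axis=axis)
        b = np.take(brain, range(1, brain.shape[axis]), axis=axis)
        n += int(np.sum(a & b))
    return n


def mesh_report(mesh: HexMesh) -> pd.DataFrame:
    """Per-part census plus global mesh QC.

    Columns: part id/name, element count, min/max element volume; the frame
    ``attrs`` carry node count, shared-node fraction and the brain-skull
    separation check (reconstructed from the voxel lattice).
    """
    if mesh.n_elements == 0:
        raise ValueError("empty mesh")
    vols = mesh.element_volumes()
    rows = []
    for pid in sorted(set(int(p) for p in np.unique(mesh.part_ids))):
        sel = mesh.part_ids == pid
        rows.append({
            "part_id": pid,
            "part_name": mesh.part_names.get(pid, f"part_{pid}"),
            "n_elements": int(sel.sum()),
            "min_volume_mm3": float(vols[sel].min()),
            "max_volume_mm3": float(vols[sel].max()),
        })
    df = pd.DataFrame(rows)
    # reconstruct the voxel grid to run the face-adjacency check
    pos = {nid: i for i, nid in enumerate(mesh.node_ids)}
    first = mesh.node_xyz[np.vectorize(pos.get)(mesh.conn[:, 0])]
    mins = mesh.node_xyz.min(axis=0)
    sp = np.array([
        np.min(np.diff(np.unique(mesh.node_xyz[:, a]))) if len(np.unique(mesh.node_xyz[:, a])) > 1 else 1.0
        for a in range(3)
    ])
    vox = np.round((first - mins) / sp).astype(int)
    grid = np.zeros(vox.max(axis=0) + 1, dtype=np.int32)
    grid[vox[:, 0], vox[:, 1], vox[:, 2]] = mesh.part_ids
    df.attrs["n_nodes"] = mesh.n_nodes
    df.attrs["shared_node_fraction"] = 1.0 - mesh.n_nodes / (8.0 * mesh.n_elements)
    df.attrs["brain_skull_adjacencies"] = _brain_skull_adjacencies(grid)
    df.attrs["sas_separation_ok"] = df.attrs["brain_skull_adjacencies"] == 0
    return df
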