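"""Build and export the 11-part voxel hexahedral head model.

Refines a phantom segmentation (SAS layer, skull shell, falx extension,
foramen opening), meshes every voxel as a shared-node hexahedral element,
assigns viscoelastic material cards (fitted brain regions + the standard
SAS card), and writes an LS-Dyna keyword deck with a half-sine neck
rotation prescribed on the rigid skull.
"""

from pathlib import Path

from brainmech import (
    MaskVolume, PhantomSpec, assign_materials, build_hex_mesh, export_keyword,
    make_anatomy, make_kinematics, merge_regions, mesh_report, refine_segmentation,
)
from brainmech.phantom import GROUP_MATERIALS, REGION_NAMES, SIX_REGION_MAPPING, VENTRICLE_LABEL

sub = make_anatomy(PhantomSpec(seed=5))
merged = merge_regions(sub.labels, SIX_REGION_MAPPING,
                       {**REGION_NAMES, VENTRICLE_LABEL: "ventricles"})
membranes = MaskVolume(sub.falx.data | sub.tentorium.data, sub.falx.spacing_mm)
seg = refine_segmentation(merged, merged.mask(VENTRICLE_LABEL), sub.dura, membranes)
mesh = build_hex_mesh(seg)
cards = assign_materials(mesh, GROUP_MATERIALS["young"])
kin = make_kinematics(omega_peak_rad_s=3.0, duration_ms=170.0)

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
deck = export_keyword(mesh, cards, kin, out / "head_model.k")
rep = mesh_report(mesh)
print(rep.to_string(index=False))
print(f"\nnodes: {rep.attrs['n_nodes']}, shared-node fraction: "
      f"{rep.attrs['shared_node_fraction']:.2f} (voxel corners shared across parts)")
print(f"brain-skull face adjacencies: {rep.attrs['brain_skull_adjacencies']} "
      "(0 means the SAS fluid layer fully separates brain from skull)")
print(f"deck written to {deck} (termination 160 ms, "
      f"peak angular velocity {kin.omega_peak:.1f} rad/s on the rigid skull)")
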