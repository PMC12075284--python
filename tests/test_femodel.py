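import numpy as np
import pytest
from scipy import ndimage

from brainmech import (
    LabelVolume,
    MaskVolume,
    PronyMaterial,
    RefinedSegmentation,
    assign_materials,
    build_hex_mesh,
    export_keyword,
    make_kinematics,
    mesh_report,
    read_keyword,
    refine_segmentation,
)
from brainmech.femodel import PART_IDS, PART_NAMES, _brain_skull_adjacencies
from brainmech.phantom import GROUP_MATERIALS


def _adjacent_pairs(a, b):
    """Count 6-connected face adjacencies between two boolean grids."""
    n = 0
    for axis in range(3):
        s1 = [slice(None)] * 3
        s2 = [slice(None)] * 3
        s1[axis] = slice(0, -1)
        s2[axis] = slice(1, None)
        n += int(np.sum(a[tuple(s1)] & b[tuple(s2)]))
        n += int(np.sum(b[tuple(s1)] & a[tuple(s2)]))
    return n


def _toy(brain_slice=slice(2, 5), gap=1):
    """7^3 toy: brain core with a `gap`-voxel dural margin."""
    shape = (7, 7, 7)
    lab = np.zeros(shape, dtype=np.int32)
    lab[brain_slice, brain_slice, brain_slice] = PART_IDS["brainstem"]
    brain = lab > 0
    dura = ndimage.binary_dilation(brain, ndimage.generate_binary_structure(3, 1), iterations=gap)
    sp = (1.0, 1.0, 1.0)
    empty = MaskVolume(np.zeros(shape, bool), sp)
    return (
        LabelVolume(lab, sp, {PART_IDS["brainstem"]: "brainstem"}),
        empty,
        MaskVolume(dura, sp),
        empty,
    )


class TestRefineSegmentation:
    def test_phantom_produces_eleven_parts(self, refined):
        assert refined.part_ids_present == sorted(PART_NAMES)

    def test_phantom_has_no_brain_skull_contact(self, refined):
        assert _brain_skull_adjacencies(refined.labels.data) == 0

    def test_toy_sas_ring_everywhere(self):
        """Brain core with a 1-voxel dural gap: every brain face neighbour
        is SAS (or brain), verified by exhaustive scan."""
        seg = refine_segmentation(*_toy())
        d = seg.labels.data
        brain = d == PART_IDS["brainstem"]
        for p in np.argwhere(brain):
            for ax in range(3):
                for dlt in (-1, 1):
                    q = p.copy()
                    q[ax] += dlt
                    if np.all((q >= 0) & (q < 7)):
                        assert d[tuple(q)] in (
                            PART_IDS["brainstem"], PART_IDS["sas"], PART_IDS["foramen"],
                        )

    def test_dura_touching_brain_repaired(self):
        """Dura hugging the brain on every face (no preliminary SAS): the
        repair still ends with zero brain-skull adjacency."""
        lab, vent, dura, mem = _toy(gap=1)
        tight_dura = MaskVolume(lab.data > 0, (1.0, 1.0, 1.0))  # dura == brain
        seg = refine_segmentation(lab, vent, tight_dura, mem)
        assert _brain_skull_adjacencies(seg.labels.data) == 0

    def test_foramen_created_under_brainstem(self, refined):
        d = refined.labels.data
        assert (d == PART_IDS["foramen"]).any()
        z_foramen = np.nonzero((d == PART_IDS["foramen"]).any(axis=(0, 1)))[0]
        stem_z = np.nonzero((d == PART_IDS["brainstem"]).any(axis=(0, 1)))[0]
        assert z_foramen.max() < stem_z.max()

    def test_falx_extension_exhausts_sas_above(self, refined):
        """Membrane columns are extended upward through the SAS: after the
        step no column top has SAS directly above it, and at least one
        column (the mid-sagittal falx) reaches the skull."""
        d = refined.labels.data
        mem = d == PART_IDS["falx_tentorium"]
        skull = d == PART_IDS["skull"]
        cols = np.argwhere(mem.any(axis=2))
        reached_skull = 0
        for ix, iy in cols:
            top = np.max(np.nonzero(mem[ix, iy])[0])
            if top + 1 < d.shape[2]:
                assert d[ix, iy, top + 1] != PART_IDS["sas"]
                if skull[ix, iy, top + 1]:
                    reached_skull += 1
        assert reached_skull > 0

    def test_missing_brainstem_rejected(self):
        lab, vent, dura, mem = _toy()
        lab2 = LabelVolume(
            np.where(lab.data > 0, PART_IDS["cerebrum_wm"], 0), (1, 1, 1),
            {PART_IDS["cerebrum_wm"]: "cerebrum_wm"},
        )
        with pytest.raises(ValueError, match="brainstem"):
            refine_segmentation(lab2, vent, dura, mem)

    def test_brain_outside_dura_rejected(self):
        lab, vent, dura, mem = _toy()
        small_dura = MaskVolume(np.zeros((7, 7, 7), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="dura"):
            refine_segmentation(lab, vent, small_dura, mem)


def _seg_from_array(arr, sp=(1.0, 1.0, 1.0)):
    return RefinedSegmentation(LabelVolume(np.asarray(arr, np.int32), sp, dict(PART_NAMES)))


class TestBuildHexMesh:
    def test_single_voxel(self):
        arr = np.zeros((1, 1, 1), int)
        arr[0, 0, 0] = 1
        mesh = build_hex_mesh(_seg_from_array(arr))
        assert mesh.n_elements == 1 and mesh.n_nodes == 8

    def test_2x2x2_block_shares_nodes(self):
        mesh = build_hex_mesh(_seg_from_array(np.full((2, 2, 2), 1)))
        assert mesh.n_elements == 8 and mesh.n_nodes == 27  # (n+1)^3 corners

    def test_two_face_adjacent_voxels(self):
        arr = np.zeros((2, 1, 1), int)
        arr[:, 0, 0] = 1
        mesh = build_hex_mesh(_seg_from_array(arr))
        assert mesh.n_elements == 2 and mesh.n_nodes == 12  # 3*2*2 lattice

    def test_node_count_equals_lattice_on_random_toys(self):
        rng = np.random.default_rng(15)
        for _ in range(3):
            arr = (rng.random((5, 4, 6)) > 0.5).astype(np.int32)
            if not arr.any():
                continue
            mesh = build_hex_mesh(_seg_from_array(arr))
            corners = set()
            for i, j, k in np.argwhere(arr):
                for di in (0, 1):
                    for dj in (0, 1):
                        for dk in (0, 1):
                            corners.add((i + di, j + dj, k + dk))
            assert mesh.n_nodes == len(corners)
            xyz = {tuple(map(float, c)) for c in corners}
            assert {tuple(p) for p in mesh.node_xyz} == xyz

    def test_volume_conservation(self, refined):
        mesh = build_hex_mesh(refined)
        vox = refined.labels.voxel_volume_mm3
        vols = mesh.element_volumes()
        assert np.all(vols > 0)
        np.testing.assert_allclose(vols, vox, rtol=1e-12)
        for pid in refined.part_ids_present:
            n_vox = int((refined.labels.data == pid).sum())
            np.testing.assert_allclose(vols[mesh.part_ids == pid].sum(), n_vox * vox, rtol=1e-12)

    def test_empty_segmentation_rejected(self):
        with pytest.raises(ValueError):
            build_hex_mesh(_seg_from_array(np.zeros((2, 2, 2), int)))


class TestAssignMaterials:
    def _mesh(self, parts=tuple(range(1, 12))):
        arr = np.zeros((len(parts), 1, 1), np.int32)
        arr[:, 0, 0] = parts
        return build_hex_mesh(_seg_from_array(arr))

    def test_sas_card_printed_values(self):
        cards = assign_materials(self._mesh(), GROUP_MATERIALS["young"])
        sas = next(c for c in cards if c.part_id == PART_IDS["sas"])
        m = sas.material
        assert m.G0_pa == 500.0
        assert m.terms == ((0.8, 0.0125),)
        assert m.rho_g_cm3 == 1.04
        assert m.K_pa == 2.19e9
        assert m.Ginf_pa == pytest.approx(100.0)  # G0 * (1 - g1)

    def test_skull_rigid(self):
        cards = assign_materials(self._mesh(), GROUP_MATERIALS["young"])
        skull = next(c for c in cards if c.part_id == PART_IDS["skull"])
        assert skull.model == "rigid"

    def test_missing_brain_material_named(self):
        mats = dict(GROUP_MATERIALS["young"])
        del mats[5]
        with pytest.raises(ValueError, match="cerebellum_gm"):
            assign_materials(self._mesh(), mats)


class TestKeywordDeck:
    @pytest.fixture()
    def deck(self, tmp_path, refined):
        mesh = build_hex_mesh(refined)
        cards = assign_materials(mesh, GROUP_MATERIALS["young"])
        kin = make_kinematics(3.0, 170.0)
        path = export_keyword(mesh, cards, kin, tmp_path / "model.k")
        return mesh, path

    def test_round_trip_lossless(self, deck):
        mesh, path = deck
        back = read_keyword(path)
        assert np.array_equal(back.node_ids, mesh.node_ids)
        np.testing.assert_allclose(back.node_xyz, mesh.node_xyz, atol=1e-6)
        assert np.array_equal(back.conn, mesh.conn)
        assert np.array_equal(back.part_ids, mesh.part_ids)

    def test_eleven_part_blocks(self, deck):
        _, path = deck
        text = path.read_text()
        assert text.count("*PART\n") == 11
        assert len(read_keyword(path).part_names) == 11

    def test_default_termination_160ms(self, deck):
        _, path = deck
        text = path.read_text()
        ctrl = text.split("*CONTROL_TERMINATION\n")[1].splitlines()[0]
        assert float(ctrl) == pytest.approx(160.0)

    def test_short_kinematics_rejected(self, tmp_path, refined):
        mesh = build_hex_mesh(refined)
        cards = assign_materials(mesh, GROUP_MATERIALS["young"])
        kin = make_kinematics(3.0, 50.0)
        with pytest.raises(ValueError, match="termination"):
            export_keyword(mesh, cards, kin, tmp_path / "m.k")


class TestMeshReport:
    def test_block_census(self):
        rep = mesh_report(build_hex_mesh(_seg_from_array(np.full((2, 2, 2), 1))))
        assert len(rep) == 1
        assert rep.iloc[0]["n_elements"] == 8
        assert rep.attrs["n_nodes"] == 27

    def test_flags_brain_skull_contact(self):
        arr = np.zeros((2, 1, 1), np.int32)
        arr[0, 0, 0] = PART_IDS["cerebrum_wm"]
        arr[1, 0, 0] = PART_IDS["skull"]
        rep = mesh_report(build_hex_mesh(_seg_from_array(arr)))
        assert rep.attrs["sas_separation_ok"] is False

    def test_phantom_passes_separation_check(self, refined):
        rep = mesh_report(build_hex_mesh(refined))
        assert rep.attrs["sas_separation_ok"] is True
        assert 0.0 < rep.attrs["shared_node_fraction"] < 1.0
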