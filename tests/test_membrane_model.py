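"""Data model: topologies, native format round-trips, reference points,
leaflet assignment, periodic geometry."""

import numpy as np
import pytest

import membramech as mm
from membramech.membrane_model import (
    MonolayerError,
    TopologyError,
    minimum_image,
    wrap_coordinates,
)


def simple_frames(coords, box=(20.0, 20.0, 60.0), n_lipids=None, dt=0.1):
    coords = np.asarray(coords, dtype=float)
    n_atoms = coords.shape[1]
    n_lipids = n_lipids or n_atoms // 3
    lipid_ids = np.repeat(np.arange(n_lipids), 3)
    names = np.tile(np.array(["P", "C2", "CT"], dtype=object), n_lipids)
    species = np.full(n_atoms, "LIP", dtype=object)
    return mm.FrameSeries(
        coords, np.tile(box, (coords.shape[0], 1)), dt, lipid_ids, species, names
    )


class TestTopology:
    def test_head_tail_overlap_rejected(self):
        with pytest.raises(TopologyError, match="overlap"):
            mm.LipidTopology("X", ["P", "C2"], [["C2", "CT"]], "P", "C2", ["CT"])

    def test_reference_atoms_must_be_heads(self):
        with pytest.raises(TopologyError):
            mm.LipidTopology("X", ["C2"], [["CT"]], "P", "C2", ["CT"])

    def test_terminal_atoms_must_be_tails(self):
        with pytest.raises(TopologyError):
            mm.LipidTopology("X", ["P", "C2"], [["CT"]], "P", "C2", ["P"])

    def test_tag_resolution(self):
        topo = mm.minimal_lipid_topology()
        assert topo.tag_atom("P") == "P"
        assert topo.tag_atom("C2") == "C2"
        with pytest.raises(TopologyError, match="C1"):
            topo.tag_atom("C1")

    def test_topology_yaml_round_trip(self, tmp_path):
        path = tmp_path / "topo.yaml"
        path.write_text(
            "LIP:\n"
            "  head_atoms: [P, C2]\n"
            "  tail_atoms: [[CT]]\n"
            "  p_atom: P\n"
            "  c2_atom: C2\n"
            "  terminal_atoms: [CT]\n"
            "  vdw_radii: {P: 2.0, C2: 2.0, CT: 2.0}\n"
        )
        topos = mm.load_topologies(path)
        assert topos["LIP"].all_atoms == ["P", "C2", "CT"]


class TestNativeFormat:
    def test_round_trip_bitwise(self, tmp_path):
        membrane = mm.make_lattice_membrane(
            n_lipids_per_leaflet=16, n_frames=2, seed=11, z_sigma=0.5, tilt_sigma=0.05
        )
        path = tmp_path / "frames.dat"
        mm.write_native_frames(membrane.frames, path)
        loaded = mm.load_frames(path, membrane.topologies, format="native")
        assert loaded.n_frames == 2
        assert len(loaded.unique_lipids) == 32
        np.testing.assert_allclose(loaded.coords, membrane.frames.coords, atol=1e-6)
        np.testing.assert_array_equal(loaded.lipid_ids, membrane.frames.lipid_ids)

    def test_unknown_residue_named_in_error(self, tmp_path):
        membrane = mm.make_lattice_membrane(n_lipids_per_leaflet=16, n_frames=1, seed=1)
        frames = membrane.frames
        frames.species[:] = "XXX"
        path = tmp_path / "bad.dat"
        mm.write_native_frames(frames, path)
        with pytest.raises(TopologyError, match="XXX"):
            mm.load_frames(path, membrane.topologies, format="native")

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.dat"
        path.write_text("# membramech native frames v1\n")
        with pytest.raises(ValueError):
            mm.load_frames(path, {}, format="native")


class TestStandardReaders:
    def test_pdb_round_trip(self, tmp_path):
        pdb = tmp_path / "mini.pdb"
        lines = []
        for model in (1, 2):
            lines.append(f"MODEL     {model}")
            lines.append(
                "CRYST1   20.000   20.000   60.000  90.00  90.00  90.00 P 1           1"
            )
            serial = 1
            for lid in range(2):
                for name, z in (("P", 40.0), ("C2", 38.0), ("CT", 25.0)):
                    x = 5.0 + 8.0 * lid + 0.1 * model
                    lines.append(
                        f"ATOM  {serial:5d} {name:<4s} LIP A{lid + 1:4d}    "
                        f"{x:8.3f}{5.0:8.3f}{z:8.3f}  1.00  0.00"
                    )
                    serial += 1
            lines.append("ENDMDL")
        lines.append("END")
        pdb.write_text("\n".join(lines) + "\n")
        topo = {"LIP": mm.minimal_lipid_topology()}
        frames = mm.load_frames(pdb, topo, format="pdb", dt=0.5)
        assert frames.n_frames == 2
        assert frames.n_atoms == 6
        assert frames.coords[0, 0, 0] == pytest.approx(5.1, abs=1e-3)
        np.testing.assert_allclose(frames.box[0], [20, 20, 60])

    def test_gro_reader(self, tmp_path):
        gro = tmp_path / "mini.gro"
        lines = ["two lipids", "6"]
        n = 1
        for lid in range(2):
            for name, z_nm in (("P", 4.0), ("C2", 3.8), ("CT", 2.5)):
                x_nm = 0.5 + 0.8 * lid
                lines.append(
                    f"{lid + 1:5d}{'LIP':<5s}{name:>5s}{n:5d}"
                    f"{x_nm:8.3f}{0.5:8.3f}{z_nm:8.3f}"
                )
                n += 1
        lines.append("   2.00000   2.00000   6.00000")
        gro.write_text("\n".join(lines) + "\n")
        topo = {"LIP": mm.minimal_lipid_topology()}
        frames = mm.load_frames(gro, topo, format="gro", dt=0.2)
        assert frames.n_frames == 1
        np.testing.assert_allclose(frames.box[0], [20.0, 20.0, 60.0])
        # nm in the file, Å in memory
        assert frames.coords[0, 0, 0] == pytest.approx(5.0, abs=1e-3)
        assert frames.coords[0, 3, 0] == pytest.approx(13.0, abs=1e-3)

    def test_xyz_with_box_comment(self, tmp_path):
        xyz = tmp_path / "mini.xyz"
        body = []
        for _ in range(2):
            body.append("6")
            body.append("box 20.0 20.0 60.0")
            for lid in range(2):
                for name, z in (("P", 40.0), ("C2", 38.0), ("CT", 25.0)):
                    body.append(f"{name} {5.0 + 8 * lid} 5.0 {z}")
        xyz.write_text("\n".join(body) + "\n")
        topo = {"LIP": mm.minimal_lipid_topology()}
        frames = mm.load_frames(xyz, topo, format="xyz")
        assert frames.n_frames == 2
        assert list(frames.unique_lipids) == [0, 1]


class TestReferencePoints:
    def test_head_point_is_p_c2_midpoint(self):
        coords = np.array([[[0, 0, 10], [0, 0, 12], [0, 0, 2]],
                           [[0, 0, 40], [0, 0, 42], [0, 0, 50]]], dtype=float)
        frames = simple_frames(coords[None, :, :].reshape(1, 6, 3))
        _, heads, tails = mm.reference_points(
            frames, {"LIP": mm.minimal_lipid_topology()}
        )
        np.testing.assert_allclose(heads[0, 0], [0, 0, 11])
        np.testing.assert_allclose(tails[0, 0], [0, 0, 2])

    def test_midpoint_equals_mean_random(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(2, 18, size=(3, 6, 3))
        frames = simple_frames(coords, box=(50.0, 50.0, 50.0))
        _, heads, _ = mm.reference_points(frames, {"LIP": mm.minimal_lipid_topology()})
        expected = 0.5 * (coords[:, 0::3, :] + coords[:, 1::3, :])
        np.testing.assert_allclose(heads, expected, atol=1e-9)

    def test_midpoint_across_periodic_boundary(self):
        coords = np.array([[[0.5, 5, 5], [19.5, 5, 5], [10, 5, 5]]], dtype=float)
        frames = simple_frames(coords, box=(20.0, 20.0, 20.0), n_lipids=1)
        _, heads, _ = mm.reference_points(frames, {"LIP": mm.minimal_lipid_topology()})
        assert heads[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_missing_reference_atom_names_offender(self):
        coords = np.zeros((1, 3, 3))
        frames = simple_frames(coords, n_lipids=1)
        frames.atom_names[0] = "PX"
        with pytest.raises(TopologyError, match="P"):
            mm.reference_points(frames, {"LIP": mm.minimal_lipid_topology()})


class TestLeafletAssignment:
    def make_bilayer(self, z_up=40.0, z_lo=20.0, shift=0.0):
        coords = np.array(
            [
                [[5, 5, z_up], [5, 5, z_up - 2], [5, 5, z_up - 10]],
                [[15, 5, z_up], [15, 5, z_up - 2], [15, 5, z_up - 10]],
                [[5, 15, z_lo], [5, 15, z_lo + 2], [5, 15, z_lo + 10]],
                [[15, 15, z_lo], [15, 15, z_lo + 2], [15, 15, z_lo + 10]],
            ],
            dtype=float,
        ).reshape(1, 12, 3) + shift
        return simple_frames(coords)

    def test_symmetric_bilayer_split(self):
        leaf = mm.assign_leaflets(self.make_bilayer(), {"LIP": mm.minimal_lipid_topology()})
        assert sorted(leaf.lipids("upper")) == [0, 1]
        assert sorted(leaf.lipids("lower")) == [2, 3]

    def test_monolayer_rejected(self):
        coords = np.array(
            [
                [[5, 5, 40], [5, 5, 38], [5, 5, 30]],
                [[15, 5, 40], [15, 5, 38], [15, 5, 30]],
            ],
            dtype=float,
        ).reshape(1, 6, 3)
        with pytest.raises(MonolayerError, match="monolayer"):
            mm.assign_leaflets(
                simple_frames(coords), {"LIP": mm.minimal_lipid_topology()}
            )

    def test_invariant_under_z_translation_and_relabeling(self):
        topo = {"LIP": mm.minimal_lipid_topology()}
        base = mm.assign_leaflets(self.make_bilayer(), topo)
        shifted = mm.assign_leaflets(
            self.make_bilayer(shift=np.array([0.0, 0.0, 7.5])), topo
        )
        assert base.leaflet == shifted.leaflet
        # permute lipid order
        frames = self.make_bilayer()
        order = np.array([2, 0, 3, 1])
        perm = np.concatenate([np.arange(lid * 3, lid * 3 + 3) for lid in order])
        permuted = mm.FrameSeries(
            frames.coords[:, perm], frames.box, frames.dt,
            frames.lipid_ids[perm], frames.species[perm], frames.atom_names[perm],
        )
        assert mm.assign_leaflets(permuted, topo).leaflet == base.leaflet

    def test_generator_labels_recovered_with_jitter(self):
        membrane = mm.make_lattice_membrane(
            n_lipids_per_leaflet=64, thickness=40.0, z_sigma=1.0, n_frames=3, seed=21
        )
        leaf = mm.assign_leaflets(membrane.frames, membrane.topologies)
        assert leaf.leaflet == membrane.leaflet_truth


class TestPeriodicGeometry:
    def test_minimum_image_matches_27_image_search(self):
        rng = np.random.default_rng(3)
        box = np.array([17.0, 23.0, 31.0])
        pts = rng.uniform(0, box, size=(30, 3))
        delta = pts[None, :, :] - pts[:, None, :]
        mic = np.linalg.norm(minimum_image(delta, box), axis=-1)
        shifts = np.array(
            [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        ) * box
        brute = np.min(
            np.linalg.norm(delta[:, :, None, :] + shifts[None, None], axis=-1), axis=2
        )
        np.testing.assert_allclose(mic, brute, atol=1e-9)

    def test_wrapping_preserves_minimum_image_distances(self):
        rng = np.random.default_rng(4)
        box = np.array([15.0, 15.0, 15.0])
        pts = rng.uniform(-30, 30, size=(40, 3))
        wrapped = wrap_coordinates(pts, box)
        d0 = np.linalg.norm(
            minimum_image(pts[None] - pts[:, None], box), axis=-1
        )
        d1 = np.linalg.norm(
            minimum_image(wrapped[None] - wrapped[:, None], box), axis=-1
        )
        np.testing.assert_allclose(d0, d1, atol=1e-9)
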