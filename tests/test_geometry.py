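"""PDB handling, symmetry-axis detection, channel profiling, RMSD."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from mifkit import geometry, synthetic
from mifkit.geometry import (StructureModel, channel_profile,
                             detect_symmetry_axis, kabsch,
                             min_intersubunit_distance, read_pdb,
                             superpose_rmsd, transform_model, write_pdb)


def pdb_line(serial, name, alt, res, chain, seq, x, y, z, elem, record="ATOM"):
    return (f"{record:<6s}{serial:5d} {name:^4s}{alt:1s}{res:<3s} {chain:1s}"
            f"{seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{10.0:6.2f}"
            f"          {elem:>2s}")


@pytest.fixture
def gate_shell():
    return synthetic.gen_trimer_shell(5.0, 2.0, 1.7)


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


class TestPDBIO:
    def test_write_read_roundtrip_is_exact(self, tmp_path):
        shell = synthetic.gen_trimer_shell(5.0, 2.0, 1.7, decimals=3)
        path = tmp_path / "shell.pdb"
        write_pdb(shell, path)
        back = read_pdb(path)
        key = ["chain", "resnum", "atom"]
        a = shell.atoms.sort_values(key).reset_index(drop=True)
        b = back.atoms.sort_values(key).reset_index(drop=True)
        np.testing.assert_array_equal(a[["x", "y", "z"]].to_numpy(),
                                      b[["x", "y", "z"]].to_numpy())
        assert list(a["chain"]) == list(b["chain"])

    def test_altloc_conformers_both_retained(self, tmp_path):
        lines = [pdb_line(1, "CA", " ", "CYS", "A", 99, 0, 0, 0, "C"),
                 pdb_line(2, "SG", "A", "CYS", "A", 99, 1.0, 0.5, 0.2, "S"),
                 pdb_line(3, "SG", "B", "CYS", "A", 99, -1.0, 0.4, 0.1, "S"),
                 "END"]
        path = tmp_path / "altloc.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_pdb(path, exclude_hetero=False)
        sg = model.atoms[model.atoms["atom"] == "SG"]
        assert sorted(sg["altloc"]) == ["A", "B"]
        assert len(sg) == 2

    def test_waters_excluded_by_default(self, tmp_path):
        lines = [pdb_line(1, "CA", " ", "GLY", "A", 1, 0, 0, 0, "C"),
                 pdb_line(2, "O", " ", "HOH", "A", 200, 5, 5, 5, "O",
                          record="HETATM"),
                 "END"]
        path = tmp_path / "wat.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_pdb(path)
        assert "HOH" not in set(model.atoms["resname"])

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError):
            read_pdb(path)


class TestSymmetryAxis:
    def test_axis_aligned_shell_recovers_z(self, gate_shell):
        axis = detect_symmetry_axis(gate_shell)
        np.testing.assert_allclose(axis.direction, [0, 0, 1], atol=1e-6)

    def test_rotated_shell_recovers_rotated_axis(self, gate_shell):
        R, t = random_rigid(5)
        rotated = transform_model(gate_shell, R, t)
        axis = detect_symmetry_axis(rotated)
        cosang = abs(np.clip(np.dot(axis.direction, R @ [0, 0, 1]), -1, 1))
        assert np.degrees(np.arccos(cosang)) < 0.1

    def test_two_chain_model_rejected(self, gate_shell):
        two = StructureModel(
            gate_shell.atoms[gate_shell.atoms["chain"] != "C"].copy(),
            vdw=gate_shell.vdw)
        with pytest.raises(ValueError, match="3 chains"):
            detect_symmetry_axis(two)

    def test_non_c3_geometry_rejected(self, gate_shell):
        # rotate chain B an extra 60 degrees: the A->B rotation becomes
        # ~180 degrees, far outside the 120 +/- 15 acceptance window
        atoms = gate_shell.atoms.copy()
        sel = atoms["chain"] == "B"
        R = Rotation.from_euler("z", 60, degrees=True).as_matrix()
        atoms.loc[sel, ["x", "y", "z"]] = (
            atoms.loc[sel, ["x", "y", "z"]].to_numpy() @ R.T)
        with pytest.raises(ValueError, match="C3-symmetric"):
            detect_symmetry_axis(StructureModel(atoms, vdw=gate_shell.vdw))


class TestChannelProfile:
    def test_uniform_shell_constant_radius(self):
        shell = synthetic.gen_trimer_shell(5.0, 0.0, 1.7)
        prof = channel_profile(shell, detect_symmetry_axis(shell))
        np.testing.assert_allclose(prof.samples["radius"], 3.3, atol=1e-9)

    def test_gate_constriction_detected(self, gate_shell):
        prof = channel_profile(gate_shell, detect_symmetry_axis(gate_shell))
        assert prof.gate_radius == pytest.approx(1.3, abs=1e-9)

    @pytest.mark.parametrize("step", [0.2, 0.1, 0.05])
    def test_gate_radius_analytic_for_fine_steps(self, gate_shell, step):
        prof = channel_profile(gate_shell, detect_symmetry_axis(gate_shell),
                               step=step)
        assert prof.gate_radius == pytest.approx(1.3, abs=1e-9)

    def test_rigid_transform_invariance(self, gate_shell):
        ref = channel_profile(gate_shell, detect_symmetry_axis(gate_shell))
        R, t = random_rigid(11)
        moved = transform_model(gate_shell, R, t)
        prof = channel_profile(moved, detect_symmetry_axis(moved))
        np.testing.assert_allclose(prof.samples["radius"],
                                   ref.samples["radius"], atol=1e-6)
        assert prof.gate_radius == pytest.approx(ref.gate_radius, abs=1e-6)


class TestInterSubunitDistance:
    def test_constructed_separation_recovered(self):
        shell = synthetic.gen_trimer_shell(8.0, 0.0, 1.7, thiol_distance=6.5)
        d, chains, altlocs = min_intersubunit_distance(shell, 4, "SG")
        assert d == pytest.approx(6.5, abs=1e-9)
        assert chains[0] != chains[1]

    def test_rigid_transform_invariance(self):
        shell = synthetic.gen_trimer_shell(8.0, 0.0, 1.7, thiol_distance=6.5)
        R, t = random_rigid(3)
        d0, _, _ = min_intersubunit_distance(shell, 4, "SG")
        d1, _, _ = min_intersubunit_distance(transform_model(shell, R, t),
                                             4, "SG")
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_single_chain_rejected(self, gate_shell):
        one = StructureModel(
            gate_shell.atoms[gate_shell.atoms["chain"] == "A"].copy(),
            vdw=gate_shell.vdw)
        with pytest.raises(ValueError, match="fewer than 2 chains"):
            min_intersubunit_distance(one, 4, "C1")

    def test_absent_atom_named_in_error(self, gate_shell):
        with pytest.raises(ValueError, match="SG.*99"):
            min_intersubunit_distance(gate_shell, 99, "SG")


class TestSuperposition:
    def test_self_rmsd_zero(self, gate_shell):
        res = superpose_rmsd(gate_shell, gate_shell, selection="C1")
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_copy_rmsd_vanishes(self, gate_shell):
        R, t = random_rigid(8)
        res = superpose_rmsd(gate_shell, transform_model(gate_shell, R, t),
                             selection="C1")
        assert res.rmsd < 1e-8

    def test_symmetry_of_rmsd(self, gate_shell):
        rng = np.random.default_rng(2)
        jittered = gate_shell.atoms.copy()
        jittered[["x", "y", "z"]] += rng.normal(0, 0.1, (len(jittered), 3))
        other = StructureModel(jittered, vdw=gate_shell.vdw)
        ab = superpose_rmsd(gate_shell, other, selection="C1").rmsd
        ba = superpose_rmsd(other, gate_shell, selection="C1").rmsd
        assert ab == pytest.approx(ba, abs=1e-10)

    def test_cyclic_chain_mapping_found_after_120_rotation(self, gate_shell):
        R = Rotation.from_euler("z", 120, degrees=True).as_matrix()
        rotated = transform_model(gate_shell, R, np.zeros(3))
        res = superpose_rmsd(gate_shell, rotated, selection="C1")
        assert res.rmsd < 1e-8

    def test_kabsch_rotation_is_proper(self):
        rng = np.random.default_rng(1)
        P = rng.uniform(-5, 5, (10, 3))
        R0, t0 = random_rigid(4)
        R, t, rmsd = kabsch(P, P @ R0.T + t0)
        assert np.linalg.det(R) == pytest.approx(1.0)
        assert rmsd < 1e-10
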