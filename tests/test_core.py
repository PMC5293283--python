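"""Structure/trajectory I/O, selections, superposition and RMSD."""

from __future__ import annotations

import io

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import mdcoord as m
from conftest import ALTLOC_PDB, MINIMAL_PDB, random_rotation


class TestReadStructure:
    def test_minimal_two_atom_fields_copied_exactly(self, minimal_structure):
        s = minimal_structure
        assert s.n_atoms == 2
        assert s.names.tolist() == ["CA", "CA"]
        assert s.resnames.tolist() == ["ALA", "GLY"]
        assert s.resids.tolist() == [1, 2]
        np.testing.assert_array_equal(
            s.coords, [[1.0, 2.0, 3.0], [4.5, -1.25, 0.125]])

    def test_altloc_policy_keeps_a_or_blank(self):
        # hand count: 6 records, 2 carry altloc B/C -> 4 retained
        n_expected = sum(1 for line in ALTLOC_PDB.splitlines()
                         if line.startswith("ATOM") and line[16] in (" ", "A"))
        s = m.read_structure(io.StringIO(ALTLOC_PDB))
        assert s.n_atoms == n_expected == 4
        assert set(s.altlocs.tolist()) <= {"", "A"}

    def test_malformed_coordinate_names_line_number(self):
        bad = MINIMAL_PDB.replace("   4.500", "  4.5.00")
        with pytest.raises(m.MDFormatError, match="line 3"):
            m.read_structure(io.StringIO(bad))

    def test_empty_source_is_an_error(self):
        with pytest.raises(m.MDFormatError):
            m.read_structure(io.StringIO("END\n"))

    def test_hetatm_metal_records_parsed(self):
        pdb = ("HETATM    1 MN    MN X   1       1.000   2.000   3.000"
               "  1.00  0.00          MN\n")
        s = m.read_structure(io.StringIO(pdb))
        assert s.het[0] and s.names[0] == "MN"


class TestTrajectoryIO:
    def test_multimodel_pdb_three_frames(self, minimal_structure, tmp_path):
        traj = m.Trajectory(minimal_structure,
                            np.stack([minimal_structure.coords + i
                                      for i in range(3)]))
        p = tmp_path / "t.pdb"
        m.write_multimodel_pdb(traj, p)
        back = m.read_trajectory(minimal_structure, p)
        assert back.n_frames == 3 and back.n_atoms == 2
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-3)

    def test_dcd_round_trip(self, hinge_trajectory, tmp_path):
        p = tmp_path / "t.dcd"
        m.write_dcd(hinge_trajectory, p)
        back = m.read_trajectory(hinge_trajectory.reference, p)
        np.testing.assert_allclose(back.frames, hinge_trajectory.frames,
                                   atol=1e-4)

    def test_xtc_read_converts_nm_to_angstrom(self, hinge_trajectory, tmp_path):
        import MDAnalysis as mda
        from MDAnalysis.coordinates.memory import MemoryReader

        traj = hinge_trajectory
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        u.load_new(traj.frames.astype(np.float32), format=MemoryReader)
        p = tmp_path / "t.xtc"
        with mda.Writer(str(p), n_atoms=traj.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
        back = m.read_trajectory(traj.reference, p)
        # XTC stores nm at 0.001 nm precision; values must come back in A
        np.testing.assert_allclose(back.frames, traj.frames, atol=0.02)

    def test_atom_count_mismatch_rejected(self, minimal_structure, tmp_path):
        other = m.make_calpha_chain(5)
        traj = m.Trajectory(other, other.coords[None])
        p = tmp_path / "t.pdb"
        m.write_multimodel_pdb(traj, p)
        with pytest.raises(m.MDFormatError, match="atoms"):
            m.read_trajectory(minimal_structure, p)


class TestSelections:
    def test_hybrid_domain_interval_arithmetic(self):
        s = m.make_calpha_chain(500, chain="B")
        dom = m.DomainDefinition("hybrid", "B", ((55, 108), (353, 434)))
        sel = m.resolve_selection(s, dom, atom_filter="CA")
        assert len(sel) == (108 - 55 + 1) + (434 - 353 + 1) == 136

    def test_expression_and_domain_agree(self, two_domain):
        sel_expr = m.resolve_selection(two_domain,
                                       "chain A and resid 1-40 and name CA")
        dom = m.DomainDefinition("a", "A", ((1, 40),))
        sel_dom = m.resolve_selection(two_domain, dom, atom_filter="CA")
        assert sel_expr.indices == sel_dom.indices

    def test_empty_selection_is_an_error(self, two_domain):
        with pytest.raises(m.SelectionError):
            m.resolve_selection(two_domain, "chain A and resid 900-950")

    def test_resolution_is_pure(self, two_domain):
        a = m.resolve_selection(two_domain, "chain B")
        b = m.resolve_selection(two_domain, "chain B")
        assert a.indices == b.indices

    def test_overlapping_domain_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            m.DomainDefinition("bad", "A", ((1, 50), (40, 60)))


class TestSuperposition:
    def test_rotated_translated_copy_fits_to_zero(self, two_domain):
        rng = np.random.default_rng(5)
        R = random_rotation(rng)
        moved = two_domain.coords @ R.T + np.array([5.0, -3.0, 2.0])
        traj = m.Trajectory(two_domain, moved[None])
        sel = m.resolve_selection(two_domain, "all")
        fitted = m.superpose_trajectory(traj, two_domain, sel)
        assert m.rmsd(fitted.frames[0], two_domain.coords) <= 1e-8

    def test_rotation_matches_quaternion_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            P = rng.normal(size=(10, 3))
            Q = rng.normal(size=(10, 3))
            R, t = m.kabsch(P, Q)
            R_oracle, _ = Rotation.align_vectors(
                Q - Q.mean(axis=0), P - P.mean(axis=0))
            np.testing.assert_allclose(R, R_oracle.as_matrix(), atol=1e-8)

    def test_mirror_image_gets_proper_rotation(self, two_domain):
        mirrored = two_domain.coords * np.array([-1.0, 1.0, 1.0])
        R, t = m.kabsch(mirrored, two_domain.coords)
        assert np.isclose(np.linalg.det(R), 1.0)
        assert m.rmsd(mirrored @ R.T + t, two_domain.coords) > 0.1

    def test_superposition_is_idempotent(self, hinge_trajectory, two_domain):
        sel = m.resolve_selection(two_domain, "chain A")
        once = m.superpose_trajectory(hinge_trajectory, two_domain, sel)
        twice = m.superpose_trajectory(once, two_domain, sel)
        assert np.abs(twice.frames - once.frames).max() < 1e-8

    def test_collinear_fit_atoms_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError, match="collinear"):
            m.kabsch(line, line + 1.0)


class TestRMSD:
    def test_identity_and_translation(self, two_domain):
        x = two_domain.coords
        assert m.rmsd(x, x) == 0.0
        shifted = x + np.array([1.0, 0.0, 0.0])
        assert np.isclose(m.rmsd(x, shifted), 1.0)
        assert m.rmsd(x, shifted, fit=True) <= 1e-8

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(13)
        a, b, c = rng.normal(size=(3, 20, 3))
        assert np.isclose(m.rmsd(a, b), m.rmsd(b, a))
        assert m.rmsd(a, c) <= m.rmsd(a, b) + m.rmsd(b, c) + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.rmsd(np.zeros((3, 3)), np.zeros((4, 3)))
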