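"""Geometric descriptors: Rg, pair distances, axes/torsions, stacking,
contacts."""

from __future__ import annotations

import numpy as np
import pytest

import mdcoord as m
from _oracles import brute_force_gyration_axes
from conftest import random_rotation


def _static_traj(structure, n_frames=1):
    return m.Trajectory(structure,
                        np.repeat(structure.coords[None], n_frames, axis=0))


class TestRadiusOfGyration:
    def test_two_points(self):
        s = m.make_calpha_chain(2)
        frames = np.zeros((1, 2, 3))
        frames[0, 1, 0] = 6.0
        rg = m.radius_of_gyration(m.Trajectory(s, frames),
                                  m.resolve_selection(s, "all"))
        assert rg.values[0] == pytest.approx(3.0)

    def test_unit_square_corners(self):
        s = m.make_calpha_chain(4)
        frames = np.array([[[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]],
                          dtype=float)
        rg = m.radius_of_gyration(m.Trajectory(s, frames),
                                  m.resolve_selection(s, "all"))
        assert rg.values[0] == pytest.approx(np.sqrt(2) / 2)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        s = m.make_calpha_chain(30)
        frames = rng.normal(scale=5.0, size=(4, 30, 3))
        rg = m.radius_of_gyration(m.Trajectory(s, frames),
                                  m.resolve_selection(s, "all"))
        for f in range(4):
            c = frames[f].mean(axis=0)
            direct = np.sqrt(np.mean(np.sum((frames[f] - c) ** 2, axis=1)))
            assert rg.values[f] == pytest.approx(direct, abs=1e-12)


class TestPairDistance:
    def test_coincident_atoms(self):
        s = m.make_calpha_chain(3)
        frames = np.zeros((2, 3, 3))
        d = m.pair_distance_series(m.Trajectory(s, frames), "A:1:CA", "A:2:CA")
        assert np.all(d.values == 0.0)

    def test_metal_particle_distance(self):
        import io
        pdb = (
            "ATOM      1  O   MET B 335      10.000   0.000   0.000"
            "  1.00  0.00           O\n"
            "HETATM    2 MN    MN X   1       0.000   0.000   0.000"
            "  1.00  0.00          MN\n")
        s = m.read_structure(io.StringIO(pdb))
        d = m.pair_distance_series(_static_traj(s), "B:335:O", "X:1:MN")
        assert d.values[0] == pytest.approx(10.0)

    def test_unresolvable_label_is_error(self, two_domain):
        with pytest.raises(m.SelectionError):
            m.pair_distance_series(_static_traj(two_domain), "Z:1:CA", "A:1:CA")


class TestPrincipalAxes:
    def test_points_on_x_axis_with_jitter(self):
        rng = np.random.default_rng(0)
        pts = np.zeros((20, 3))
        pts[:, 0] = np.linspace(-10, 10, 20)
        pts[:, 1:] = rng.normal(scale=0.01, size=(20, 2))
        c, axes, evals = m.principal_axes(pts)
        assert abs(axes[0, 0]) > 0.999
        assert axes[0, np.argmax(np.abs(axes[0]))] > 0   # sign rule

    def test_matches_gyration_tensor_oracle(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(50, 3)) * np.array([3.0, 2.0, 1.0])
        _, axes, evals = m.principal_axes(pts)
        evals_o, axes_o = brute_force_gyration_axes(pts)
        np.testing.assert_allclose(evals, evals_o, atol=1e-10)
        for k in range(3):
            assert abs(np.dot(axes[k], axes_o[k])) == pytest.approx(1.0,
                                                                    abs=1e-10)

    def test_collinear_points_rejected(self):
        pts = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(ValueError):
            m.principal_axes(pts)


class TestInterdomainTorsion:
    def test_static_structure_constant_series(self, two_domain,
                                              two_domain_selections):
        sel_a, sel_b = two_domain_selections
        tor = m.interdomain_torsion_series(_static_traj(two_domain, 5),
                                           sel_a, sel_b)
        assert np.ptp(tor.values) == 0.0

    def test_hinge_sweep_recovery(self, hinge_trajectory,
                                  two_domain_selections):
        sel_a, sel_b = two_domain_selections
        tor = m.interdomain_torsion_series(hinge_trajectory, sel_a, sel_b)
        assert abs(np.ptp(tor.values) - 60.0) < 0.5

    def test_invariant_under_global_rotation(self, hinge_trajectory,
                                             two_domain_selections):
        sel_a, sel_b = two_domain_selections
        rng = np.random.default_rng(9)
        frames = np.stack([hinge_trajectory.frames[f] @ random_rotation(rng).T
                           + rng.normal(size=3)
                           for f in range(hinge_trajectory.n_frames)])
        moved = m.Trajectory(hinge_trajectory.reference, frames)
        a = m.interdomain_torsion_series(hinge_trajectory, sel_a, sel_b).values
        b = m.interdomain_torsion_series(moved, sel_a, sel_b).values
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_series_within_0_180(self, hinge_trajectory,
                                 two_domain_selections):
        sel_a, sel_b = two_domain_selections
        tor = m.interdomain_torsion_series(hinge_trajectory, sel_a, sel_b)
        assert tor.values.min() >= 0.0 and tor.values.max() <= 180.0


class TestStacking:
    def test_parallel_rings_at_5A(self):
        traj = m.generate_ring_pair(m.RingPairSpec(5.0, 0.0, 1, 0))
        sg = m.stacking_series(traj, ("A", 1), ("B", 1))
        assert sg.distance[0] == pytest.approx(5.0, abs=1e-9)
        assert sg.theta[0] == pytest.approx(0.0, abs=1e-6)
        assert sg.paired[0]
        # exactly parallel rings sit below the 1.2-degree angle window
        assert not sg.stacked[0]

    def test_far_rings_not_paired(self):
        traj = m.generate_ring_pair(m.RingPairSpec(15.0, 30.0, 1, 0))
        sg = m.stacking_series(traj, ("A", 1), ("B", 1))
        assert not sg.paired[0] and not sg.stacked[0]

    @pytest.mark.parametrize("d,theta,stacked", [
        (4.9, 25.8, True),        # crystal-like packed pair
        (4.89, 25.8, False),      # just below the distance window
        (10.41, 25.8, False),     # just above the distance window
        (7.0, 1.1, False),        # below the angle window
        (7.0, 89.95, False),      # above the angle window (T-shaped limit)
        (10.4, 89.9, True),       # inclusive upper corners
    ])
    def test_stacking_window_boundaries(self, d, theta, stacked):
        traj = m.generate_ring_pair(m.RingPairSpec(d, theta, 1, 0))
        sg = m.stacking_series(traj, ("A", 1), ("B", 1))
        assert bool(sg.stacked[0]) is stacked

    def test_theta_independent_of_atom_order_and_normal_sign(self):
        traj = m.generate_ring_pair(m.RingPairSpec(6.0, 40.0, 1, 0))
        s = traj.reference
        perm = np.concatenate([np.random.default_rng(0).permutation(6),
                               6 + np.random.default_rng(1).permutation(6)])
        shuffled = s.subset(perm)
        traj2 = m.Trajectory(shuffled, traj.frames[:, perm, :])
        a = m.stacking_series(traj, ("A", 1), ("B", 1)).theta[0]
        b = m.stacking_series(traj2, ("A", 1), ("B", 1)).theta[0]
        assert a == pytest.approx(b, abs=1e-9)

    def test_non_aromatic_residue_is_error(self, two_domain):
        with pytest.raises(m.SelectionError, match="aromatic"):
            m.stacking_series(_static_traj(two_domain), ("A", 1), ("A", 2))

    def test_invariant_under_rigid_motion(self):
        traj = m.generate_ring_pair(m.RingPairSpec(6.5, 30.0, 4, 1,
                                                   jitter_sigma=0.05))
        rng = np.random.default_rng(2)
        frames = np.stack([traj.frames[f] @ random_rotation(rng).T + 7.0
                           for f in range(traj.n_frames)])
        moved = m.Trajectory(traj.reference, frames)
        a = m.stacking_series(traj, ("A", 1), ("B", 1))
        b = m.stacking_series(moved, ("A", 1), ("B", 1))
        np.testing.assert_allclose(a.distance, b.distance, atol=1e-9)
        np.testing.assert_allclose(a.theta, b.theta, atol=1e-7)


def _hbond_fixture(distances, angle_deg=180.0):
    """Donor N, hydrogen and acceptor O with per-frame D-A distance and
    D-H...A angle."""
    import io
    pdb = (
        "ATOM      1  N   ASN B 215       0.000   0.000   0.000"
        "  1.00  0.00           N\n"
        "ATOM      2  H   ASN B 215       1.000   0.000   0.000"
        "  1.00  0.00           H\n"
        "ATOM      3  OD1 ASP F1495       2.800   0.000   0.000"
        "  1.00  0.00           O\n")
    s = m.read_structure(io.StringIO(pdb))
    F = len(distances)
    frames = np.repeat(s.coords[None], F, axis=0)
    th = np.deg2rad(180.0 - angle_deg)
    for f, d in enumerate(distances):
        # place acceptor at the requested distance, preserving the angle at H
        frames[f, 2] = frames[f, 1] + (d - 1.0) * np.array(
            [np.cos(th), np.sin(th), 0.0])
    return m.Trajectory(s, frames)


class TestContacts:
    def test_ideal_hbond_full_occupancy(self):
        traj = _hbond_fixture([2.8] * 10)
        out = m.hbond_occupancy(traj, [("B:215:N", "F:1495:OD1", "B:215:H")])
        assert out[0].occupancy == 100.0

    def test_long_distance_not_hbond(self):
        traj = _hbond_fixture([4.0] * 10)
        out = m.hbond_occupancy(traj, [("B:215:N", "F:1495:OD1")])
        assert out[0].occupancy == 0.0

    def test_angle_criterion_applies_with_hydrogen(self):
        traj = _hbond_fixture([2.8] * 10, angle_deg=90.0)
        with_h = m.hbond_occupancy(traj,
                                   [("B:215:N", "F:1495:OD1", "B:215:H")])
        without_h = m.hbond_occupancy(traj, [("B:215:N", "F:1495:OD1")])
        assert with_h[0].occupancy == 0.0
        assert without_h[0].occupancy == 100.0

    def test_constructed_38_percent_occupancy(self):
        distances = [2.8] * 38 + [5.0] * 62
        traj = _hbond_fixture(distances)
        out = m.hbond_occupancy(traj, [("B:215:N", "F:1495:OD1")])
        assert out[0].occupancy == pytest.approx(38.0)

    def test_occupancy_additive_over_replicas(self):
        t1 = _hbond_fixture([2.8] * 30 + [5.0] * 70)   # 30%
        t2 = _hbond_fixture([2.8] * 50 + [5.0] * 50)   # 50%
        out = m.hbond_occupancy([t1, t2], [("B:215:N", "F:1495:OD1")])
        assert out[0].occupancy == pytest.approx(40.0)

    def test_salt_bridge_autoscan(self):
        import io
        pdb = (
            "ATOM      1  NH1 ARG F1493       0.000   0.000   0.000"
            "  1.00  0.00           N\n"
            "ATOM      2  CA  ARG F1493       5.000   5.000   0.000"
            "  1.00  0.00           C\n"
            "ATOM      3  OD1 ASP A 150       3.500   0.000   0.000"
            "  1.00  0.00           O\n"
            "ATOM      4  OD2 ASP A 150       4.800   0.000   0.000"
            "  1.00  0.00           O\n")
        s = m.read_structure(io.StringIO(pdb))
        traj = _static_traj(s, 4)
        sel_fn = m.resolve_selection(s, "chain F")
        sel_av = m.resolve_selection(s, "chain A")
        out = m.salt_bridge_occupancy(traj, sel_fn, sel_av)
        assert len(out) == 1
        assert out[0].occupancy == 100.0       # OD1 within 4.0 A

    def test_filter_at_one_percent(self):
        traj = _hbond_fixture([2.8] * 1 + [5.0] * 199)  # 0.5%
        out = m.hbond_saltbridge_occupancy(
            traj, hbond_pairs=[("B:215:N", "F:1495:OD1")])
        assert out == []
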