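"""Pore profiling, Mg²⁺-site quadrilateral geometry, gate distance, helix RMSD."""

import numpy as np
import pytest
from scipy.optimize import fmin
from scipy.spatial.transform import Rotation

from hyperbar import synth
from hyperbar.pore import (
    gate_distance,
    helix_align_rmsd,
    pore_profile,
    site_geometry,
)
from hyperbar.trajio import (
    Atom,
    Frame,
    IndexGroup,
    SelectionError,
    Topology,
    select,
)

from conftest import make_frame, make_topology


def cylinder_system(radius_fn, z_range=(2.0, 5.0), dz=0.05, n_phi=24, vdw=0.2):
    atoms, pos = [], []
    serial = 1
    for z in np.arange(z_range[0], z_range[1] + 1e-9, dz):
        for phi in np.linspace(0, 2 * np.pi, n_phi, endpoint=False):
            r = radius_fn(z)
            atoms.append(Atom(serial=serial, name="CA", residue_name="ALA",
                              residue_number=serial, chain_id="A", element="C",
                              vdw_radius=vdw))
            pos.append((5 + r * np.cos(phi), 5 + r * np.sin(phi), z))
            serial += 1
    top = Topology(atoms)
    return top, Frame(0.0, np.array(pos), np.array([10.0, 10.0, 10.0])), \
        IndexGroup("wall", tuple(range(1, serial)))


class TestPoreProfile:
    def test_uniform_cylinder_radius(self):
        top, fr, grp = cylinder_system(lambda z: 1.0)
        prof = pore_profile(fr, top, grp, (2.3, 4.7), 0.1)
        np.testing.assert_allclose(prof.radius, 0.8, atol=0.01)
        np.testing.assert_allclose(prof.center_xy, 5.0, atol=0.01)

    def test_vdw_shrink_increases_radius_by_delta(self):
        delta = 0.05
        top_a, fr, grp = cylinder_system(lambda z: 1.0, vdw=0.2)
        top_b, _, _ = cylinder_system(lambda z: 1.0, vdw=0.2 - delta)
        a = pore_profile(fr, top_a, grp, (2.3, 4.7), 0.1)
        b = pore_profile(fr, top_b, grp, (2.3, 4.7), 0.1)
        np.testing.assert_allclose(b.radius - a.radius, delta, atol=1e-6)

    def test_pinched_ring_locates_minimum(self):
        def r_of(z):
            return 0.5 if abs(z - 3.5) < 0.1 else 1.0

        top, fr, grp = cylinder_system(r_of)
        prof = pore_profile(fr, top, grp, (2.3, 4.7), 0.1)
        assert prof.min_radius == pytest.approx(0.3, abs=0.02)
        assert abs(prof.min_radius_z - 3.5) <= 0.25

    def test_empty_range_warns(self):
        top, fr, grp = cylinder_system(lambda z: 1.0)
        with pytest.warns(UserWarning):
            prof = pore_profile(fr, top, grp, (8.0, 9.0), 0.1)
        assert len(prof.z) == 0

    def test_rotation_about_axis_invariant(self):
        top, fr, grp = cylinder_system(lambda z: 1.0 + 0.1 * np.sin(2.0), n_phi=18)
        base = pore_profile(fr, top, grp, (2.3, 4.7), 0.1)
        R = Rotation.from_euler("z", 37, degrees=True).as_matrix()
        c = np.array([5.0, 5.0, 0.0])
        rot = Frame(0.0, (fr.coordinates - c) @ R.T + c, fr.box)
        prof = pore_profile(rot, top, grp, (2.3, 4.7), 0.1)
        np.testing.assert_allclose(prof.radius, base.radius, atol=0.01)

    def test_surface_points_on_the_inscribed_circles(self):
        top, fr, grp = cylinder_system(lambda z: 1.0)
        prof = pore_profile(fr, top, grp, (2.3, 4.7), 0.2)
        for k, z in enumerate(prof.z):
            ring = prof.surface[np.isclose(prof.surface[:, 2], z)]
            d = np.linalg.norm(ring[:, :2] - prof.center_xy[k], axis=1)
            np.testing.assert_allclose(d, prof.radius[k], atol=1e-9)

    def test_synthetic_channel_pinch_recovered(self, default_system):
        spec, top, traj = default_system
        gt = synth.ground_truth(spec)
        chains = np.isin(top.chain_ids, ("A", "B", "C", "D"))
        wall = IndexGroup("wall", tuple(int(i) + 1 for i in np.nonzero(chains)[0]))
        prof = pore_profile(traj.frames[0], top, wall, spec.tmd_z, 0.1)
        assert prof.min_radius == pytest.approx(gt["pore_min_radius"], abs=0.08)
        assert abs(prof.min_radius_z - gt["pore_min_radius_z"]) <= 0.25


def square(edge_nm=1.0, angle=0.0, center=(4.0, 4.0)):
    h = edge_nm / 2
    pts = np.array([[h, h], [-h, h], [-h, -h], [h, -h]])
    R = np.array([[np.cos(angle), -np.sin(angle)],
                  [np.sin(angle), np.cos(angle)]])
    pts = pts @ R.T + center
    return np.column_stack([pts, np.full(4, 5.0)])


def site_fixture(xyz):
    top = make_topology(4, name="OD1")
    return top, make_frame(xyz), IndexGroup("od1", (1, 2, 3, 4))


class TestSiteGeometry:
    def test_unit_square(self):
        top, fr, grp = site_fixture(square(1.0))
        g = site_geometry(fr, top, grp)
        np.testing.assert_allclose(g.sides_A, 10.0, atol=1e-9)
        assert g.diagonal_ratio == pytest.approx(1.0)
        assert g.crossing_angle_deg == pytest.approx(90.0)

    def test_rhombus(self):
        xyz = np.column_stack([
            np.array([[1.0, 0], [0, 0.5], [-1.0, 0], [0, -0.5]]) + 4.0,
            np.full(4, 5.0),
        ])
        top, fr, grp = site_fixture(xyz)
        g = site_geometry(fr, top, grp)
        np.testing.assert_allclose(sorted(g.diagonals_A), [10.0, 20.0])
        assert g.diagonal_ratio == pytest.approx(0.5)
        assert g.crossing_angle_deg == pytest.approx(90.0)
        np.testing.assert_allclose(g.sides_A, np.hypot(10, 5), atol=1e-9)

    def test_rotated_square_identical_metrics(self):
        top, fr0, grp = site_fixture(square(1.0))
        _, fr1, _ = site_fixture(square(1.0, angle=np.pi / 4, center=(6.0, 2.0)))
        a = site_geometry(fr0, top, grp)
        b = site_geometry(fr1, top, grp)
        np.testing.assert_allclose(sorted(a.sides_A), sorted(b.sides_A), atol=1e-9)
        assert a.diagonal_ratio == pytest.approx(b.diagonal_ratio)
        assert a.crossing_angle_deg == pytest.approx(b.crossing_angle_deg)

    def test_relabeling_invariance(self):
        xyz = square(1.0)
        top, fr, _ = site_fixture(xyz)
        perm = [2, 0, 3, 1]
        top_p, fr_p, grp = site_fixture(xyz[perm])
        a = site_geometry(fr, top, grp)
        b = site_geometry(fr_p, top_p, grp)
        np.testing.assert_allclose(sorted(a.sides_A), sorted(b.sides_A), atol=1e-9)
        assert a.crossing_angle_deg == pytest.approx(b.crossing_angle_deg)

    def test_wrong_atom_count_rejected(self):
        top = make_topology(3, name="OD1")
        fr = make_frame(np.full((3, 3), 4.0))
        with pytest.raises(SelectionError, match="4 atoms"):
            site_geometry(fr, top, IndexGroup("g", (1, 2, 3)))

    def test_collinear_projection_flagged(self):
        xyz = np.column_stack([
            np.array([[0.0, 0], [0.5, 0], [1.0, 0], [0.5, 1.0]]) + 4.0,
            np.full(4, 5.0),
        ])
        top, fr, grp = site_fixture(xyz)
        assert site_geometry(fr, top, grp).degenerate

    def test_synthetic_site_rectangle(self, default_system):
        spec, top, traj = default_system
        gt = synth.ground_truth(spec)
        od1 = select(top, name="OD1", group_name="site")
        g = site_geometry(traj.frames[0], top, od1)
        assert g.diagonal_ratio == pytest.approx(1.0, abs=0.12)
        np.testing.assert_allclose(
            sorted(g.diagonals_A), [gt["site_diagonal_A"]] * 2, atol=1.2
        )
        np.testing.assert_allclose(
            sorted(g.sides_A)[:2], [gt["site_sides_A"][1]] * 2, atol=1.2
        )


class TestGateDistance:
    def gate_system(self, d_nm):
        atoms = [
            Atom(serial=i + 1, name="CA", residue_name="GLU", residue_number=299,
                 chain_id=c, element="C")
            for i, c in enumerate("AC")
        ]
        top = Topology(atoms)
        fr = make_frame([[5 - d_nm / 2, 5, 5], [5 + d_nm / 2, 5, 5]])
        return top, fr

    def test_open_state_reference_distance(self):
        top, fr = self.gate_system(3.36)
        d, state = gate_distance(fr, top)
        assert d == pytest.approx(33.6)
        assert state == "open"

    def test_coincident_atoms_closed(self):
        top, fr = self.gate_system(0.0)
        d, state = gate_distance(fr, top)
        assert d == 0.0 and state == "closed"

    def test_boundary_counts_as_open(self):
        top, fr = self.gate_system(2.8)
        d, state = gate_distance(fr, top)
        assert d == pytest.approx(28.0) and state == "open"

    def test_missing_residue_rejected(self, small_system):
        top, traj = small_system
        with pytest.raises(SelectionError):
            gate_distance(traj.frames[0], top, residue_number=7777)

    def test_synthetic_gate_matches_construction(self, default_system):
        spec, top, traj = default_system
        gt = synth.ground_truth(spec)
        d, state = gate_distance(traj.frames[0], top)
        assert d == pytest.approx(gt["gate_distance_A"], abs=1.5)
        assert state == "open"


def ideal_helix(n_res=12, rise=0.15, radius=0.23, per_turn=3.6):
    t = np.arange(n_res) * 2 * np.pi / per_turn
    return np.column_stack([radius * np.cos(t), radius * np.sin(t),
                            rise * np.arange(n_res)])


class TestHelixAlignRmsd:
    def test_identical_zero(self):
        h = ideal_helix()
        assert helix_align_rmsd(h, h) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_zero(self):
        h = ideal_helix()
        R = Rotation.from_euler("xyz", [40, -25, 110], degrees=True).as_matrix()
        assert helix_align_rmsd(h @ R.T + 3.0, h) == pytest.approx(0.0, abs=1e-8)

    def test_unwound_tail_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        a = ideal_helix()
        b = a.copy()
        b[-4:] += rng.normal(0, 0.08, (4, 3))  # partially unwound top turn
        R = Rotation.random(random_state=1).as_matrix()
        b = b @ R.T + 1.0
        mine = helix_align_rmsd(b, a)

        mob = b - b.mean(0)
        ref = a - a.mean(0)

        def rmsd_of(angles):
            M = Rotation.from_euler("zyz", angles).as_matrix()
            return np.sqrt((((mob @ M.T) - ref) ** 2).sum(1).mean())

        grid = np.linspace(0, 2 * np.pi, 21, endpoint=False)
        half = np.linspace(0, np.pi, 11)
        best = min(
            ((a1, b1, c1) for a1 in grid for b1 in half for c1 in grid),
            key=rmsd_of,
        )
        oracle = rmsd_of(fmin(rmsd_of, best, xtol=1e-9, ftol=1e-12, disp=False))
        assert abs(mine - oracle * 10.0) < 1e-3

    def test_count_mismatch_rejected(self):
        with pytest.raises(SelectionError):
            helix_align_rmsd(ideal_helix(10), ideal_helix(11))
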