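"""Superposition, helix axis, center of mass, domain rotation, distances."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ggcx_motion import (
    align_trajectory,
    atom_distance,
    center_of_mass,
    domain_rotation,
    gen_rotated_pair,
    gen_template,
    helix_axis,
    kabsch,
    select,
)
from ggcx_motion.geometry import DegeneracyError
from ggcx_motion.model_io import AtomSelection, Trajectory


def random_rigid(rng):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return R, t


class TestKabsch:
    def test_identity_when_already_superposed(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        res = kabsch(pts, pts)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(res.translation, 0.0, atol=1e-10)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_exact_rotation_and_translation(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(8, 3))
        R90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = (ref - [1, 2, 3]) @ R90  # ref = mobile @ R90.T ... rigid copy
        res = kabsch(mobile, ref)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        angle = np.degrees(
            np.arccos(np.clip((np.trace(res.rotation) - 1) / 2, -1, 1))
        )
        assert angle == pytest.approx(90.0, abs=1e-8)
        np.testing.assert_allclose(res.apply(mobile), ref, atol=1e-9)

    def test_noisy_rotation_recovery_within_2_degrees(self):
        rng = np.random.default_rng(42)
        pts = rng.normal(scale=5.0, size=(10, 3))
        R_true, t_true = random_rigid(rng)
        noisy = pts @ R_true.T + t_true + rng.normal(scale=0.1, size=pts.shape)
        res = kabsch(pts, noisy)
        # angle of R_recovered @ R_true^T measures the recovery error
        diff = Rotation.from_matrix(res.rotation @ R_true.T).magnitude()
        assert np.degrees(diff) < 2.0

    def test_rmsd_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(3)
        mobile = rng.normal(size=(12, 3))
        ref = rng.normal(size=(12, 3))
        base = kabsch(mobile, ref).rmsd
        for _ in range(5):
            R, t = random_rigid(rng)
            moved = mobile @ R.T + t
            assert kabsch(moved, ref).rmsd == pytest.approx(base, abs=1e-9)

    def test_collinear_points_raise(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegeneracyError):
            kabsch(line, line + 1.0)

    def test_weights_shift_the_fit(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(6, 3))
        mobile = ref + rng.normal(scale=0.5, size=(6, 3))
        w = np.array([10.0, 1, 1, 1, 1, 1])
        res_w = kabsch(mobile, ref, weights=w)
        moved = res_w.apply(mobile)
        # the heavily weighted atom lands closer than under uniform weights
        res_u = kabsch(mobile, ref)
        d_w = np.linalg.norm(moved[0] - ref[0])
        d_u = np.linalg.norm(res_u.apply(mobile)[0] - ref[0])
        assert d_w <= d_u + 1e-12


class TestAlignTrajectory:
    def _rigid_copies_traj(self, template, n=6, seed=5):
        rng = np.random.default_rng(seed)
        base = template.positions
        frames = [base]
        for _ in range(n - 1):
            R, t = random_rigid(rng)
            frames.append(base @ R.T + t)
        return Trajectory(template, np.array(frames), np.arange(n, dtype=float))

    def test_rigid_copies_collapse_onto_reference(self, template, selections):
        traj = self._rigid_copies_traj(template)
        aligned = align_trajectory(traj, selections["core"])
        for fi in range(traj.n_frames):
            np.testing.assert_allclose(aligned.frames[fi], traj.frames[0], atol=1e-6)

    def test_idempotent(self, template, selections, noiseless_run):
        _, traj, _, _ = noiseless_run
        once = align_trajectory(traj, selections["core"])
        twice = align_trajectory(once, selections["core"])
        np.testing.assert_allclose(twice.frames, once.frames, atol=1e-6)

    def test_never_increases_core_rmsd(self, template, selections):
        rng = np.random.default_rng(6)
        base = template.positions
        frames = [base]
        for _ in range(5):
            R, t = random_rigid(rng)
            frames.append((base + rng.normal(scale=0.4, size=base.shape)) @ R.T + t)
        traj = Trajectory(template, np.array(frames), np.arange(6, dtype=float))
        idx = selections["core"].indices
        aligned = align_trajectory(traj, selections["core"])
        for fi in range(traj.n_frames):
            before = np.sqrt(((traj.frames[fi][idx] - traj.frames[0][idx]) ** 2).sum(1).mean())
            after = np.sqrt(((aligned.frames[fi][idx] - traj.frames[0][idx]) ** 2).sum(1).mean())
            assert after <= before + 1e-9

    def test_reference_frame_untouched(self, template, selections, noiseless_run):
        _, traj, _, _ = noiseless_run
        aligned = align_trajectory(traj, selections["core"], ref_frame=0)
        np.testing.assert_array_equal(aligned.frames[0], traj.frames[0])


class TestHelixAxis:
    def test_collinear_points_give_unit_z(self):
        pts = np.outer(np.arange(6.0), [0, 0, 1.0])
        np.testing.assert_allclose(helix_axis(pts), [0, 0, 1], atol=1e-12)

    def test_sign_flips_under_order_reversal(self):
        pts = np.outer(np.arange(6.0), [0, 0, 1.0])
        np.testing.assert_allclose(helix_axis(pts[::-1]), [0, 0, -1], atol=1e-12)

    def test_ideal_alpha_helix_axis_within_1_degree(self):
        # long enough that the finite-length tilt of the principal axis
        # (weighted phase sums that do not cancel) drops below a degree
        i = np.arange(36)
        phase = np.radians(100.0 * i)
        coords = np.column_stack(
            [2.3 * np.cos(phase), 2.3 * np.sin(phase), 1.5 * i]
        )
        ax = helix_axis(coords)
        angle = np.degrees(np.arccos(np.clip(ax @ [0, 0, 1], -1, 1)))
        assert angle < 1.0

    def test_output_is_unit_norm(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            pts = np.outer(np.arange(8.0), rng.normal(size=3)) + rng.normal(
                scale=0.3, size=(8, 3)
            )
            assert abs(np.linalg.norm(helix_axis(pts)) - 1) < 1e-9

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 4"):
            helix_axis(np.zeros((3, 3)))

    def test_isotropic_set_is_degenerate(self):
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1.0]]
        )
        with pytest.raises(DegeneracyError):
            helix_axis(pts)


class TestCenterOfMass:
    def test_geometric_mean_of_two_atoms(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        np.testing.assert_allclose(center_of_mass(coords), [1, 0, 0])

    def test_single_atom_is_its_own_com(self, template):
        sel = AtomSelection(np.array([0]))
        np.testing.assert_allclose(
            center_of_mass(template.positions, sel),
            template.positions[0],
        )

    def test_mass_weighted_carbon_oxygen(self, template):
        # C at origin, O at (0,0,2): z_com = 2*15.999/(12.011+15.999)
        from ggcx_motion.model_io import Atom, Structure

        st = Structure(
            [
                Atom(1, "C", "LIG", 1, "A", "C", (0.0, 0.0, 0.0)),
                Atom(2, "O", "LIG", 1, "A", "O", (0.0, 0.0, 2.0)),
            ]
        )
        sel = AtomSelection(np.array([0, 1]))
        com = center_of_mass(st.positions, sel, st, mass_weighted=True)
        assert com[2] == pytest.approx(2 * 15.999 / (12.011 + 15.999), abs=1e-9)
        # ~8/7 with nominal integer masses; standard weights shift it slightly
        assert com[2] == pytest.approx(8 / 7, abs=1e-3)

    def test_unknown_element_errors_when_mass_weighted(self):
        from ggcx_motion.model_io import Atom, Structure

        st = Structure([Atom(1, "X1", "LIG", 1, "A", "Xx", (0.0, 0.0, 0.0))] * 3)
        sel = AtomSelection(np.array([0, 1, 2]))
        with pytest.raises(KeyError, match="unknown element"):
            center_of_mass(st.positions, sel, st, mass_weighted=True)

    def test_empty_selection_errors(self, template):
        with pytest.raises(ValueError, match="empty selection"):
            center_of_mass(template.positions, AtomSelection(np.array([], dtype=int)))


class TestDomainRotation:
    CORE = "resid 1-199 and name CA"
    DOMAIN = "resid 500-599 and name CA"

    def test_self_comparison_is_zero_with_undefined_axis(self, template):
        res = domain_rotation(template, template, self.CORE, self.DOMAIN)
        assert res.angle_deg == pytest.approx(0.0, abs=1e-6)
        assert res.axis is None

    def test_exact_implanted_rotation(self, template):
        a, b = gen_rotated_pair(template, self.DOMAIN, angle_deg=5.0, seed=8)
        res = domain_rotation(a, b, self.CORE, self.DOMAIN)
        assert res.angle_deg == pytest.approx(5.0, abs=1e-6)
        assert res.n_domain_pairs == 20

    def test_noisy_rotation_recovery_within_1_degree(self, template):
        # cap + helix together span ~30 A, so all three rotational degrees
        # of freedom are well conditioned against 0.2 A coordinate noise
        wide = "resid 200-599 and name CA"
        a, b = gen_rotated_pair(template, wide, angle_deg=12.0, noise_sigma=0.2, seed=9)
        res = domain_rotation(a, b, self.CORE, wide)
        assert res.angle_deg == pytest.approx(12.0, abs=1.0)

    def test_angle_symmetric_in_argument_order(self, template):
        a, b = gen_rotated_pair(template, self.DOMAIN, angle_deg=7.0, seed=10)
        ab = domain_rotation(a, b, self.CORE, self.DOMAIN).angle_deg
        ba = domain_rotation(b, a, self.CORE, self.DOMAIN).angle_deg
        assert ab == pytest.approx(ba, abs=1e-6)


class TestAtomDistance:
    def test_known_separation(self, template):
        from ggcx_motion.model_io import Atom, Structure

        st = Structure(
            [
                Atom(1, "NZ", "LYS", 217, "A", "N", (0.0, 0.0, 0.0)),
                Atom(2, "CD", "GLU", 53, "B", "C", (0.0, 0.0, 12.0)),
            ]
        )
        assert atom_distance(st, ("A", 217, "NZ"), ("B", 53, "CD")) == pytest.approx(12.0)
        assert atom_distance(st, ("A", 217, "NZ"), ("A", 217, "NZ")) == 0.0

    def test_missing_atom_reports_the_query(self, template):
        from ggcx_motion.model_io import SelectionError

        with pytest.raises(SelectionError, match="999"):
            atom_distance(template, ("A", 999, "CA"), ("A", 1, "CA"))

    def test_invariant_under_rigid_transform(self, template):
        rng = np.random.default_rng(11)
        d0 = atom_distance(template, ("A", 1, "CA"), ("A", 246, "CA"))
        R, t = random_rigid(rng)
        moved = template.with_positions(template.positions @ R.T + t)
        d1 = atom_distance(moved, ("A", 1, "CA"), ("A", 246, "CA"))
        assert d1 == pytest.approx(d0, abs=1e-9)
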