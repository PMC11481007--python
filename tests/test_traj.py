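"""Superposition, RMSD/RMSF, hydrogen bonds, contacts, PCA and FEL."""

import numpy as np
import pytest

from pharmfunnel import synth
from pharmfunnel.chemio import AtomMeta, Trajectory
from pharmfunnel.traj import (
    KB,
    TrajAnalysisError,
    contact_count_series,
    free_energy_landscape,
    hydrogen_bonds,
    hydrogen_bonds_frame,
    kabsch_superpose,
    min_distance_series,
    pca_covariance,
    project,
    rmsd_series,
    rmsf,
)


def _rot(rng):
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _traj(frames, elements=None, residues=None):
    n = frames[0].shape[0]
    elements = elements or ["C"] * n
    residues = residues or [("MOL", 1)] * n
    meta = [
        AtomMeta(f"{e}{i}", e, rn, rnum, "A")
        for i, (e, (rn, rnum)) in enumerate(zip(elements, residues))
    ]
    return Trajectory([np.asarray(f, dtype=float) for f in frames], meta)


class TestKabsch:
    def test_identical_coordinates_zero_rmsd(self, rng):
        x = rng.normal(size=(10, 3))
        rot, trans, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered_exactly(self, rng):
        x = rng.normal(size=(25, 3))
        moved = x @ _rot(rng).T + np.array([3.0, -2.0, 7.0])
        rot, trans, rmsd = kabsch_superpose(x, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_rotation_always_proper_even_for_reflections(self, rng):
        x = rng.normal(size=(10, 3))
        mirrored = x * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = kabsch_superpose(x, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_matches_scipy_alignment(self, rng):
        """Independent oracle: scipy's least-squares rotation alignment."""
        from scipy.spatial.transform import Rotation

        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        _, _, rmsd = kabsch_superpose(a, b)
        ac, bc = a - a.mean(0), b - b.mean(0)
        rot_sp, rssd = Rotation.align_vectors(ac, bc)
        rmsd_sp = np.sqrt(
            np.mean(np.sum((rot_sp.apply(bc) - ac) ** 2, axis=1))
        )
        assert rmsd == pytest.approx(rmsd_sp, abs=1e-9)

    def test_superposition_never_increases_rmsd(self, rng):
        for _ in range(10):
            a = rng.normal(size=(12, 3))
            b = a + rng.normal(scale=0.8, size=(12, 3))
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            _, _, fitted = kabsch_superpose(a, b)
            assert fitted <= raw + 1e-12

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        with pytest.raises(TrajAnalysisError):
            kabsch_superpose(line, line)
        with pytest.raises(TrajAnalysisError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdRmsf:
    def test_zero_wobble_series_identically_zero(self, pocket_pose):
        t = synth.make_trajectory(pocket_pose, 10, wobble_sd=0.0, seed=0)
        np.testing.assert_allclose(rmsd_series(t), 0.0, atol=1e-12)

    def test_wobbling_ligand_stays_below_stability_cutoff(self, pocket_pose):
        """A 0.5 A wobble keeps ligand RMSD well under the 3 A criterion."""
        t = synth.make_trajectory(pocket_pose, 200, wobble_sd=0.5, seed=1)
        lig = t.select(lambda m: m.residue_name == "LIG")
        rec = t.select(lambda m: m.residue_name != "LIG")
        series = rmsd_series(t, selection=lig, fit_selection=rec)
        assert series.mean() < 3.0

    def test_rigid_translation_gives_zero_rmsf_after_fitting(self, pocket_pose):
        t0 = synth.make_trajectory(pocket_pose, 20, wobble_sd=0.0, seed=0)
        frames = [f + i * np.array([0.5, 0.2, -0.1]) for i, f in enumerate(t0.frames)]
        t = Trajectory(frames, t0.meta)
        np.testing.assert_allclose(rmsf(t), 0.0, atol=1e-10)

    def test_empty_selection_raises(self, pocket_pose):
        t = synth.make_trajectory(pocket_pose, 5, wobble_sd=0.1, seed=0)
        with pytest.raises(TrajAnalysisError):
            rmsd_series(t, selection=np.array([], dtype=int))


class TestHydrogenBonds:
    def _linear_ohO(self, da=2.8):
        # O-H...O, perfectly linear: H on the donor-acceptor axis
        coords = np.array(
            [[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [da, 0.0, 0.0]]
        )
        return coords, ["O", "H", "O"]

    def test_ideal_linear_geometry_is_one_bond(self):
        coords, elements = self._linear_ohO(2.8)
        bonds = hydrogen_bonds_frame(
            coords, elements, donors=np.array([0]), acceptors=np.array([2])
        )
        assert len(bonds) == 1
        b = bonds[0]
        assert b.da_distance == pytest.approx(2.8)
        assert b.ha_distance == pytest.approx(2.8 - 0.96)
        assert b.hda_angle == pytest.approx(0.0, abs=1e-9)

    def test_long_distance_is_no_bond(self):
        coords, elements = self._linear_ohO(4.5)
        bonds = hydrogen_bonds_frame(
            coords, elements, donors=np.array([0]), acceptors=np.array([2])
        )
        assert bonds == []

    def test_bent_geometry_beyond_angle_cutoff_rejected(self):
        # H placed 45 degrees off the D-A axis
        coords = np.array(
            [[0.0, 0.0, 0.0],
             [0.96 * np.cos(np.pi / 4), 0.96 * np.sin(np.pi / 4), 0.0],
             [2.8, 0.0, 0.0]]
        )
        bonds = hydrogen_bonds_frame(
            coords, ["O", "H", "O"], donors=np.array([0]), acceptors=np.array([2])
        )
        assert bonds == []

    def test_planted_set_counts_exactly_k(self):
        """Three donors, two within criteria -> exactly 2 bonds."""
        coords = np.array(
            [
                [0.0, 0.0, 0.0], [0.96, 0.0, 0.0],      # donor 1 + H (bonded)
                [0.0, 6.0, 0.0], [0.96, 6.0, 0.0],      # donor 2 + H (bonded)
                [0.0, 12.0, 0.0], [0.96, 12.0, 0.0],    # donor 3 + H (too far)
                [3.0, 0.0, 0.0], [3.2, 6.0, 0.0], [8.0, 12.0, 0.0],
            ]
        )
        elements = ["N", "H", "O", "H", "N", "H", "O", "O", "O"]
        bonds = hydrogen_bonds_frame(
            coords, elements,
            donors=np.array([0, 2, 4]), acceptors=np.array([6, 7, 8]),
        )
        assert len(bonds) == 2

    def test_trajectory_counts_and_missing_hydrogens(self, pocket_pose):
        coords, elements = self._linear_ohO(2.8)
        frames = [coords, coords + 10.0]  # rigid shift preserves the bond
        t = _traj(frames, elements=elements)
        counts, per_frame = hydrogen_bonds(
            t, donors=np.array([0]), acceptors=np.array([2])
        )
        assert counts.tolist() == [1, 1]
        bare = _traj([np.zeros((2, 3)) + [[0, 0, 0], [3, 0, 0]]], ["O", "O"])
        with pytest.raises(TrajAnalysisError, match="hydrogens"):
            hydrogen_bonds(bare, donors=np.array([0]), acceptors=np.array([1]))


class TestDistancesContacts:
    def test_two_atoms_at_three_angstrom(self):
        t = _traj([np.array([[0, 0, 0], [3, 0, 0]])])
        a, b = np.array([0]), np.array([1])
        assert min_distance_series(t, a, b)[0] == pytest.approx(3.0)
        assert contact_count_series(t, a, b)[0] == 1

    def test_separated_groups_have_zero_contacts(self):
        t = _traj([np.array([[0, 0, 0], [10, 0, 0]])])
        assert contact_count_series(t, np.array([0]), np.array([1]))[0] == 0

    def test_equals_double_loop_oracle(self, rng):
        coords = rng.uniform(0, 10, size=(30, 3))
        t = _traj([coords])
        a, b = np.arange(20), np.arange(20, 30)
        mind = min_distance_series(t, a, b)[0]
        cnt = contact_count_series(t, a, b, cutoff=4.0)[0]
        brute_min, brute_cnt = np.inf, 0
        for i in a:
            for j in b:
                d = np.linalg.norm(coords[i] - coords[j])
                brute_min = min(brute_min, d)
                brute_cnt += d <= 4.0
        assert mind == pytest.approx(brute_min)
        assert cnt == brute_cnt

    def test_overlapping_groups_rejected(self):
        t = _traj([np.zeros((3, 3))])
        with pytest.raises(TrajAnalysisError):
            min_distance_series(t, np.array([0, 1]), np.array([1, 2]))


class TestPca:
    def test_single_planted_mode_dominates(self, pocket_pose):
        t = synth.make_mode_trajectory(
            pocket_pose, 200, amplitudes=(4.0,), noise_sd=0.0, seed=5
        )
        vals, vecs, fracs = pca_covariance(t, superpose=False)
        assert fracs[0] >= 0.99

    def test_two_planted_modes_cover_95_percent(self, pocket_pose):
        t = synth.make_mode_trajectory(
            pocket_pose, 300, amplitudes=(3.0, 1.5), noise_sd=0.01, seed=6
        )
        _, _, fracs = pca_covariance(t, superpose=False)
        assert fracs[0] + fracs[1] >= 0.95

    def test_isotropic_noise_has_no_dominant_mode(self, pocket_pose):
        t = synth.make_trajectory(pocket_pose, 500, wobble_sd=1.0, seed=7)
        _, _, fracs = pca_covariance(t, superpose=False)
        assert fracs[0] < 3.0 * fracs[fracs > 0].mean()

    def test_eigenvectors_orthonormal(self, pocket_pose):
        t = synth.make_mode_trajectory(pocket_pose, 50, seed=8)
        _, vecs, _ = pca_covariance(t)
        gram = vecs.T @ vecs
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_projection_shape_and_variance_ordering(self, pocket_pose):
        t = synth.make_mode_trajectory(pocket_pose, 100, seed=9)
        vals, vecs, _ = pca_covariance(t, superpose=False)
        pts = project(t, vecs, superpose=False)
        assert pts.shape == (100, 2)
        assert pts[:, 0].var() >= pts[:, 1].var()

    def test_too_few_frames_raise(self, pocket_pose):
        t = synth.make_trajectory(pocket_pose, 2, wobble_sd=0.1, seed=0)
        with pytest.raises(TrajAnalysisError):
            pca_covariance(t)


class TestFreeEnergyLandscape:
    def test_uniform_occupancy_gives_zero_surface(self):
        # one point per bin of a 4x4 grid
        xs, ys = np.meshgrid(np.arange(4) + 0.5, np.arange(4) + 0.5)
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        fel = free_energy_landscape(pts, bins=4)
        np.testing.assert_allclose(fel.G, 0.0, atol=1e-12)

    def test_two_bin_boltzmann_inversion(self):
        """P = 0.8/0.2 at 300 K -> dG = kT ln 4 = 0.8265 kcal/mol."""
        pts = np.array([[0.25, 0.5]] * 80 + [[0.75, 0.5]] * 20)
        fel = free_energy_landscape(pts, bins=(2, 1), temperature=300.0)
        dG = fel.G[1, 0] - fel.G[0, 0]
        assert dG == pytest.approx(KB * 300.0 * np.log(4.0), abs=1e-6)
        assert dG == pytest.approx(0.8265, abs=5e-4)

    def test_minimum_is_zero_at_modal_bin(self, rng):
        pts = rng.normal(size=(2000, 2))
        fel = free_energy_landscape(pts, bins=16)
        assert fel.G.min() == 0.0
        assert fel.G[fel.minimum_bin] == 0.0

    def test_gaussian_sampling_single_global_minimum_at_mode(self, rng):
        pts = rng.normal(loc=[2.0, -1.0], scale=0.5, size=(5000, 2))
        fel = free_energy_landscape(pts, bins=12)
        i, j = fel.minimum_bin
        x_mode = 0.5 * (fel.x_edges[i] + fel.x_edges[i + 1])
        y_mode = 0.5 * (fel.y_edges[j] + fel.y_edges[j + 1])
        assert abs(x_mode - 2.0) < 0.5
        assert abs(y_mode + 1.0) < 0.5
        assert (fel.G == 0.0).sum() == 1

    def test_empty_bins_capped_finite(self):
        pts = np.array([[0.0, 0.0], [10.0, 10.0]])
        fel = free_energy_landscape(pts, bins=8, temperature=300.0)
        assert np.isfinite(fel.G).all()
        cap = fel.G[fel.counts > 0].max() + KB * 300.0
        assert fel.G[fel.counts == 0].max() == pytest.approx(cap)

    def test_zero_bins_rejected(self):
        with pytest.raises(TrajAnalysisError):
            free_energy_landscape(np.zeros((5, 2)), bins=0)
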