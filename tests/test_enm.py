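"""ANM Hessian/modes against dense analytic oracles; Kabsch superposition
and RMSF properties; PDB round-trips."""

import numpy as np
import pytest

from frapdyn.enm import (
    AnisotropicNetworkModel,
    StructureModel,
    Trajectory,
    build_anm_hessian,
    compute_modes,
    compute_rmsf,
    kabsch_rotation,
    mode_mobility,
    read_structure,
    read_trajectory,
    superpose_to_first,
    write_structure,
    write_trajectory,
)
from frapdyn.synthetic import make_toy_structure, simulate_trajectory

from _oracles import dense_anm_reference, dimer_hessian


def _random_structure(rng, n=20, spread=10.0):
    # rejection-free: random points, minimum separation enforced by retry
    while True:
        coords = rng.uniform(-spread, spread, size=(n, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > 1.0:
            return coords


class TestHessian:
    def test_dimer_matches_explicit_6x6(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        h = build_anm_hessian(coords, cutoff=15.0, gamma=1.0)
        np.testing.assert_allclose(h, dimer_hessian(1.0, 1.0), atol=1e-12)
        evals = np.linalg.eigvalsh(h)
        assert evals[-1] == pytest.approx(2.0, abs=1e-10)
        assert np.all(np.abs(evals[:-1]) < 1e-10)

    def test_translations_are_null_vectors(self):
        rng = np.random.default_rng(0)
        coords = _random_structure(rng)
        h = build_anm_hessian(coords, cutoff=12.0)
        for axis in range(3):
            v = np.zeros(3 * len(coords))
            v[axis::3] = 1.0
            assert np.max(np.abs(h @ v)) < 1e-10

    def test_no_contact_beyond_cutoff(self):
        h = build_anm_hessian(np.array([[0.0, 0, 0], [16.0, 0, 0]]), cutoff=15.0)
        assert np.all(h == 0.0)

    def test_inclusive_cutoff(self):
        h = build_anm_hessian(np.array([[0.0, 0, 0], [15.0, 0, 0]]), cutoff=15.0)
        assert np.any(h != 0.0)

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_anm_hessian(np.array([[0.0, 0, 0], [0.0, 0, 0]]))

    def test_isolated_node_warns(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [100.0, 0, 0]])
        with pytest.warns(UserWarning, match="isolated"):
            build_anm_hessian(coords, cutoff=15.0)

    def test_symmetric_psd_on_random_structures(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            coords = _random_structure(rng, n=15)
            h = build_anm_hessian(coords, cutoff=12.0)
            np.testing.assert_allclose(h, h.T, atol=1e-12)
            assert np.linalg.eigvalsh(h).min() >= -1e-8


class TestModes:
    def test_dimer_single_nontrivial_mode(self):
        h = build_anm_hessian(np.array([[0.0, 0, 0], [1.0, 0, 0]]), gamma=1.5)
        modes = compute_modes(h, n_nontrivial=10)
        assert modes.n_zero_modes == 5  # collinear pair: 3 trans + 2 rot
        assert modes.n_modes == 1
        assert modes.truncated
        assert modes.eigenvalues[0] == pytest.approx(2 * 1.5, rel=1e-10)

    def test_triangle_has_six_zero_and_three_nontrivial(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        h = build_anm_hessian(coords, cutoff=5.0)
        modes = compute_modes(h, n_nontrivial=10)
        assert modes.n_zero_modes == 6
        assert modes.n_modes == 3
        ref_evals, _ = dense_anm_reference(coords, cutoff=5.0)
        np.testing.assert_allclose(modes.eigenvalues, ref_evals[6:], rtol=1e-10)

    def test_generic_toy_has_six_zero_modes(self):
        s = make_toy_structure("helix", 30)
        modes = compute_modes(build_anm_hessian(s.ca_coords))
        assert modes.n_zero_modes == 6

    def test_matches_independent_dense_reference(self):
        s = make_toy_structure("helix", 25)
        modes = compute_modes(build_anm_hessian(s.ca_coords, cutoff=15.0))
        ref_evals, _ = dense_anm_reference(s.ca_coords, cutoff=15.0)
        np.testing.assert_allclose(modes.eigenvalues, ref_evals[6:16], rtol=1e-10)

    def test_sparse_solver_agrees_with_dense(self):
        s = make_toy_structure("helix", 50)
        h = build_anm_hessian(s.ca_coords)
        dense = compute_modes(h, solver="dense")
        sparse = compute_modes(h, solver="sparse")
        np.testing.assert_allclose(sparse.eigenvalues, dense.eigenvalues, rtol=1e-8)
        for k in range(dense.n_modes):
            dot = abs(dense.eigenvectors[:, k] @ sparse.eigenvectors[:, k])
            assert dot == pytest.approx(1.0, abs=1e-6)  # up to sign

    def test_eigenvectors_orthonormal(self):
        s = make_toy_structure("helix", 30)
        modes = compute_modes(build_anm_hessian(s.ca_coords))
        gram = modes.eigenvectors.T @ modes.eigenvectors
        np.testing.assert_allclose(gram, np.eye(modes.n_modes), atol=1e-8)


class TestMobility:
    def test_dimer_stretch_mode_equal_amplitudes(self):
        h = build_anm_hessian(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        prof = mode_mobility(compute_modes(h), 1)
        np.testing.assert_allclose(prof.values, [1 / np.sqrt(2)] * 2, atol=1e-10)

    def test_unit_norm_profile(self):
        s = make_toy_structure("two_domain_linker", 40)
        anm = AnisotropicNetworkModel().fit(s)
        prof = anm.mobility(1)
        assert np.sum(prof.values**2) == pytest.approx(1.0, abs=1e-10)

    def test_linker_mobility_exceeds_domains(self):
        s = make_toy_structure("two_domain_linker", 40)
        anm = AnisotropicNetworkModel().fit(s)
        chains = np.array([r[0] for r in s.residue_ids])
        v = anm.mobility(1).values
        assert np.median(v[chains == "L"]) > np.median(v[chains != "L"])

    def test_rotation_invariance(self):
        s = make_toy_structure("two_domain_linker", 40)
        rot = kabsch_rotation(
            np.eye(3), np.array([[0, 1, 0], [0, 0, 1.0], [1, 0, 0]])
        )  # a proper rotation
        rotated = s.ca_coords @ rot.T + np.array([5.0, -3.0, 2.0])
        v1 = AnisotropicNetworkModel().fit(s.ca_coords).mobility(1).values
        v2 = AnisotropicNetworkModel().fit(rotated).mobility(1).values
        np.testing.assert_allclose(v1, v2, atol=1e-8)

    def test_mode_index_out_of_range(self):
        h = build_anm_hessian(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        modes = compute_modes(h)
        with pytest.raises(ValueError):
            mode_mobility(modes, 2)


class TestSuperposition:
    def _rigid_copies(self, n_frames=5, seed=0):
        s = make_toy_structure("helix", 20)
        return simulate_trajectory(
            s, np.zeros(20), rigid_jitter=(30.0, 5.0), n_frames=n_frames, seed=seed
        )

    def test_removes_pure_rigid_motion(self):
        traj = self._rigid_copies()
        aligned = superpose_to_first(traj, selection="ca")
        for f in range(traj.n_frames):
            rmsd = np.sqrt(np.mean(np.sum((aligned.frames[f] - aligned.frames[0]) ** 2, axis=1)))
            assert rmsd <= 1e-8

    def test_identity_trajectory_unchanged(self):
        s = make_toy_structure("helix", 15)
        traj = Trajectory(
            frames=np.repeat(s.ca_coords[None], 3, axis=0),
            residue_ids=list(s.residue_ids),
        )
        aligned = superpose_to_first(traj, selection="ca")
        np.testing.assert_allclose(aligned.frames, traj.frames, atol=1e-12)

    def test_mirror_image_keeps_proper_rotation(self):
        s = make_toy_structure("helix", 20)
        mirrored = s.ca_coords * np.array([-1.0, 1.0, 1.0])
        traj = Trajectory(
            frames=np.stack([s.ca_coords, mirrored]),
            residue_ids=list(s.residue_ids),
        )
        aligned = superpose_to_first(traj, selection="ca")
        # a helix is chiral: no proper rotation can superpose its mirror
        rmsd = np.sqrt(np.mean(np.sum((aligned.frames[1] - aligned.frames[0]) ** 2, axis=1)))
        assert rmsd > 0.5
        rot = kabsch_rotation(
            mirrored - mirrored.mean(0), s.ca_coords - s.ca_coords.mean(0)
        )
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        traj = Trajectory(
            frames=np.repeat(line[None], 2, axis=0),
            residue_ids=[("A", i, "GLY") for i in range(5)],
        )
        with pytest.raises(ValueError, match="collinear"):
            superpose_to_first(traj, selection="ca")


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        s = make_toy_structure("helix", 10)
        traj = Trajectory(
            frames=np.repeat(s.ca_coords[None], 4, axis=0),
            residue_ids=list(s.residue_ids),
        )
        assert np.all(compute_rmsf(traj).values == 0.0)

    def test_two_frame_displacement(self):
        base = make_toy_structure("helix", 10).ca_coords
        shifted = base.copy()
        shifted[0, 0] += 2.0  # atom 0 at ±1 Å around its mean
        traj = Trajectory(
            frames=np.stack([base, shifted]),
            residue_ids=[("A", i, "ALA") for i in range(10)],
        )
        rmsf = compute_rmsf(traj).values
        assert rmsf[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(rmsf[1:] == 0.0)

    def test_gaussian_displacement_recovers_sigma_sqrt3(self):
        s = make_toy_structure("helix", 12)
        sigma = 0.1
        traj = simulate_trajectory(
            s, np.full(12, sigma), rigid_jitter=(0.0, 0.0), n_frames=1000, seed=3
        )
        rmsf = compute_rmsf(traj).values
        np.testing.assert_allclose(rmsf, sigma * np.sqrt(3), rtol=0.05)

    def test_single_frame_rejected(self):
        s = make_toy_structure("helix", 10)
        with pytest.raises(ValueError):
            Trajectory(frames=s.ca_coords[None], residue_ids=list(s.residue_ids))


class TestPdbIO:
    def test_toy_roundtrip_at_pdb_precision(self, tmp_path):
        s = make_toy_structure("two_domain_linker", 40)
        path = tmp_path / "toy.pdb"
        write_structure(s, path)
        back = read_structure(path)
        assert back.n_residues == 40
        assert [r[0] for r in back.residue_ids] == [r[0] for r in s.residue_ids]
        np.testing.assert_allclose(back.ca_coords, s.ca_coords, atol=1.5e-3)

    def test_handwritten_three_residue_pdb(self, tmp_path):
        pdb = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "tiny.pdb"
        path.write_text(pdb)
        s = read_structure(path)
        assert s.n_residues == 3
        np.testing.assert_allclose(s.ca_coords[:, 0], [0.0, 3.8, 7.6], atol=1e-6)

    def test_altloc_duplicates_resolve_to_first(self, tmp_path):
        pdb = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.50  0.00           C\n"
            "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        path = tmp_path / "altloc.pdb"
        path.write_text(pdb)
        s = read_structure(path)
        assert s.n_residues == 2
        np.testing.assert_allclose(s.ca_coords[0], [0.0, 0.0, 0.0], atol=1e-6)

    def test_trajectory_roundtrip(self, tmp_path):
        s = make_toy_structure("helix", 12)
        traj = simulate_trajectory(s, np.full(12, 0.3), n_frames=4, seed=1)
        path = tmp_path / "ens.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path, selection="ca")
        assert back.n_frames == 4
        assert back.n_atoms == 12
        np.testing.assert_allclose(back.frames, traj.frames, atol=1.5e-3)
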