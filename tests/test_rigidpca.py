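import numpy as np
import pytest

from clampmf import colvars, rigidpca, structio, toysystems
from clampmf.rigidpca import (
    PCAResult,
    RigidBodyModel,
    export_mode_arrows,
    project_onto_modes,
    read_pca,
    rigid_pca,
    strip_internal_motion,
    write_mode_arrows_pdb,
    write_pca,
)
from clampmf.structio import Selection, Trajectory, read_pdb_trajectory, rmsd


def planted_dirs_on_used(dirs, used):
    sub = dirs.reshape(3, -1, 3)[:, used, :].reshape(3, -1)
    return sub / np.linalg.norm(sub, axis=1, keepdims=True)


class TestStripInternalMotion:
    def test_rigid_input_is_fixed_point(self, clamshell_dataset, clamshell_model):
        ct, params, _, _ = clamshell_dataset
        clean = toysystems.ClamshellToyParams(
            bend_amplitude=params.bend_amplitude,
            twist_amplitude=params.twist_amplitude,
            rock_amplitude=params.rock_amplitude,
            jitter_sigma=0.0,
            seed=params.seed,
        )
        traj = toysystems.generate_clamshell_trajectory(clean, 50).trajectory
        ref = traj.topology  # generator reference is exactly rigid
        model = RigidBodyModel(
            clamshell_model.dom1, clamshell_model.dom2, clamshell_model.hinge, ref
        )
        out = strip_internal_motion(traj, model)
        np.testing.assert_allclose(out.frames, traj.frames, atol=1e-9)

    def test_substitution_forces_rigidity(self, clamshell_dataset, clamshell_model):
        ct, _, _, _ = clamshell_dataset
        out = strip_internal_motion(ct.trajectory, clamshell_model)
        ref = rigidpca.make_average_reference(ct.trajectory, clamshell_model)
        for sel in (clamshell_model.dom1, clamshell_model.dom2):
            idx = sel.atom_indices
            for f in (0, out.n_frames // 2, out.n_frames - 1):
                assert rmsd(out.frames[f][idx], ref.coords[idx], superpose=True) < 1e-9

    def test_stripped_angle_tracks_planted(self, clamshell_dataset, clamshell_model):
        ct, _, _, _ = clamshell_dataset
        stripped = strip_internal_motion(ct.trajectory, clamshell_model)
        spec = colvars.ColvarSpec(
            "interdomain_angle",
            {
                "dom1": clamshell_model.dom1,
                "dom2": clamshell_model.dom2,
                "hinge": clamshell_model.hinge,
            },
        )
        series = colvars.colvar_timeseries(stripped, spec)
        assert np.max(np.abs(series.values - ct.truth["angle"])) < 1.0

    def test_hinge_passthrough(self, clamshell_dataset, clamshell_model):
        ct, _, _, _ = clamshell_dataset
        out = strip_internal_motion(ct.trajectory, clamshell_model)
        idx = clamshell_model.hinge.atom_indices
        np.testing.assert_array_equal(out.frames[:, idx], ct.trajectory.frames[:, idx])


@pytest.fixture(scope="module")
def clamshell_pca(clamshell_dataset, clamshell_model):
    ct, _, _, _ = clamshell_dataset
    stripped = strip_internal_motion(ct.trajectory, clamshell_model)
    return stripped, rigid_pca(stripped, clamshell_model)


class TestRigidPCA:
    def test_single_planted_direction_rank_one(self):
        rng = np.random.default_rng(20)
        base = toysystems.make_clamshell_structure(toysystems.ClamshellToyParams(seed=9))
        coords = base.coords
        n = len(base)
        direction = rng.normal(size=(n, 3))
        # keep dom1 fixed so alignment is a no-op
        direction[:24] = 0.0
        direction /= np.linalg.norm(direction)
        amp = 0.3 * np.sin(2 * np.pi * np.arange(100) / 100)
        frames = coords[None] + amp[:, None, None] * direction[None]
        traj = Trajectory(base, frames, np.arange(100.0))
        d1 = Selection(np.arange(20))
        hg = Selection(np.arange(20, 24))
        d2 = Selection(np.arange(24, 44))
        model = RigidBodyModel(d1, d2, hg)
        pca = rigid_pca(traj, model, backbone_only=False, angle_sign_convention=False)
        assert pca.eigenvalues[0] / pca.total_variance > 0.999
        cos = abs(np.dot(pca.eigenvectors[0], direction.ravel()))
        assert cos > 0.999

    def test_static_trajectory_zero_eigenvalues(self, clamshell_model, clamshell_dataset):
        ct, _, _, _ = clamshell_dataset
        frames = np.repeat(ct.trajectory.frames[:1], 5, axis=0)
        traj = Trajectory(ct.trajectory.topology, frames, np.arange(5.0))
        pca = rigid_pca(traj, clamshell_model, angle_sign_convention=False)
        np.testing.assert_allclose(pca.eigenvalues, 0.0, atol=1e-12)

    def test_orthonormal_eigenvectors(self, clamshell_pca):
        _, pca = clamshell_pca
        gram = pca.eigenvectors @ pca.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_variance_conserved(self, clamshell_pca):
        stripped, pca = clamshell_pca
        # trace of the aligned covariance equals the eigenvalue sum
        frames = stripped.frames[:, pca.atom_indices, :]
        aligned = rigidpca._align_frames(frames, pca.align_reference, pca.align_indices)
        x = (aligned - aligned.mean(axis=0)).reshape(len(aligned), -1)
        trace = np.sum(x * x) / len(aligned)
        assert pca.total_variance == pytest.approx(trace, rel=1e-8)

    def test_planted_modes_recovered(self, clamshell_dataset, clamshell_pca):
        _, _, dirs, target = clamshell_dataset
        _, pca = clamshell_pca
        sub = planted_dirs_on_used(dirs, pca.atom_indices)
        for m in range(3):
            cos = max(abs(np.dot(pca.eigenvectors[m], sub[k])) for k in range(3))
            assert cos > 0.95

    def test_eigenvalue_ratios_match_planted_amplitudes(
        self, clamshell_dataset, clamshell_pca
    ):
        _, _, _, target = clamshell_dataset
        _, pca = clamshell_pca
        expected = target**2 / 2  # sinusoid variance = amplitude^2 / 2
        for m in (1, 2):
            assert pca.eigenvalues[m] / pca.eigenvalues[0] == pytest.approx(
                expected[m] / expected[0], rel=0.1
            )

    def test_two_orthogonal_modes_variance_ratio(self):
        base = toysystems.make_clamshell_structure(toysystems.ClamshellToyParams(seed=9))
        coords = base.coords
        n = len(base)
        rng = np.random.default_rng(21)
        d_a = rng.normal(size=(n, 3))
        d_a[:24] = 0.0
        d_a /= np.linalg.norm(d_a)
        d_b = rng.normal(size=(n, 3))
        d_b[:24] = 0.0
        d_b -= np.dot(d_b.ravel(), d_a.ravel()) * d_a
        d_b /= np.linalg.norm(d_b)
        i = np.arange(400)
        amp_a = 0.4 * np.sin(2 * np.pi * 3 * i / 400)
        amp_b = 0.2 * np.sin(2 * np.pi * 5 * i / 400)
        frames = coords[None] + amp_a[:, None, None] * d_a + amp_b[:, None, None] * d_b
        traj = Trajectory(base, frames, i.astype(float))
        model = RigidBodyModel(
            Selection(np.arange(20)),
            Selection(np.arange(24, 44)),
            Selection(np.arange(20, 24)),
        )
        pca = rigid_pca(traj, model, backbone_only=False, angle_sign_convention=False)
        assert pca.eigenvalues[0] / pca.eigenvalues[1] == pytest.approx(4.0, rel=0.02)

    def test_invariant_under_global_rigid_motion(self, clamshell_dataset, clamshell_model):
        ct, _, _, _ = clamshell_dataset
        stripped = strip_internal_motion(ct.trajectory, clamshell_model)
        short = Trajectory(
            stripped.topology, stripped.frames[:100], stripped.times[:100]
        )
        pca0 = rigid_pca(short, clamshell_model, angle_sign_convention=False)
        rot = np.array(
            [
                [0.36, 0.48, -0.8],
                [-0.8, 0.6, 0.0],
                [0.48, 0.64, 0.6],
            ]
        )  # proper rotation
        moved = Trajectory(
            short.topology,
            short.frames @ rot.T + np.array([1.0, -2.0, 0.5]),
            short.times,
        )
        pca1 = rigid_pca(moved, clamshell_model, angle_sign_convention=False)
        np.testing.assert_allclose(pca0.eigenvalues, pca1.eigenvalues, atol=1e-8)
        # modes live in the data-defined alignment frame, which co-rotates:
        # rotating pca0's modes by the applied rotation must recover pca1's
        for m in range(3):
            rotated = (pca0.eigenvectors[m].reshape(-1, 3) @ rot.T).ravel()
            cos = abs(np.dot(rotated, pca1.eigenvectors[m]))
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_mode1_sign_tracks_opening_angle(self, clamshell_dataset, clamshell_pca):
        ct, _, _, _ = clamshell_dataset
        stripped, pca = clamshell_pca
        proj = project_onto_modes(stripped, pca, 1)[0]
        corr = np.corrcoef(proj.values, ct.truth["angle"])[0, 1]
        assert corr > 0.9

    def test_too_few_frames(self, clamshell_dataset, clamshell_model):
        ct, _, _, _ = clamshell_dataset
        traj = Trajectory(
            ct.trajectory.topology, ct.trajectory.frames[:1], ct.trajectory.times[:1]
        )
        with pytest.raises(ValueError, match="2 frames"):
            rigid_pca(traj, clamshell_model)


class TestProjection:
    def test_reconstruction_with_all_modes_is_exact(self, clamshell_pca):
        stripped, pca = clamshell_pca
        series = project_onto_modes(stripped, pca, pca.n_modes)
        coeffs = np.stack([s.values for s in series], axis=1)  # (F, M)
        recon = coeffs @ pca.eigenvectors  # (F, 3N)
        frames = stripped.frames[:, pca.atom_indices, :]
        aligned = rigidpca._align_frames(frames, pca.align_reference, pca.align_indices)
        x = (aligned - pca.mean_coordinates).reshape(len(aligned), -1)
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_mean_frame_projects_to_zero(self, clamshell_pca):
        stripped, pca = clamshell_pca
        traj = Trajectory(
            stripped.topology,
            np.repeat(stripped.frames.mean(axis=0)[None], 2, axis=0),
            np.array([0.0, 1.0]),
        )
        # project the PCA mean itself: rebuild full-atom frame holding the mean
        frames = traj.frames.copy()
        frames[:, pca.atom_indices, :] = pca.mean_coordinates
        traj = Trajectory(stripped.topology, frames, traj.times)
        series = project_onto_modes(traj, pca, 3)
        for s in series:
            np.testing.assert_allclose(s.values, 0.0, atol=1e-9)

    def test_single_mode_sinusoid_correlates(self, clamshell_model):
        p = toysystems.ClamshellToyParams(bend_amplitude=5.0, jitter_sigma=0.002, seed=6)
        ct = toysystems.generate_clamshell_trajectory(p, 300)
        top = ct.trajectory.topology
        model = RigidBodyModel(
            structio.select_residues(top, ct.dom1_ranges),
            structio.select_residues(top, ct.dom2_ranges),
            structio.select_residues(top, ct.hinge_ranges),
        )
        stripped = strip_internal_motion(ct.trajectory, model)
        pca = rigid_pca(stripped, model)
        proj = project_onto_modes(stripped, pca, 1)[0]
        corr = np.corrcoef(proj.values, ct.truth["bend"])[0, 1]
        assert abs(corr) > 0.99

    def test_n_modes_capped(self, clamshell_pca):
        _, pca = clamshell_pca
        with pytest.raises(ValueError, match="modes"):
            project_onto_modes(None, pca, pca.n_modes + 1)


class TestModeArrows:
    def test_unit_norm_forced(self, clamshell_pca, clamshell_dataset):
        ct, _, _, _ = clamshell_dataset
        _, pca = clamshell_pca
        scale = 0.7
        plus, minus = export_mode_arrows(pca, ct.trajectory.topology, 0, scale)
        disp = plus.coords - pca.mean_coordinates
        assert np.sqrt(np.sum(disp**2)) == pytest.approx(scale, rel=1e-9)
        np.testing.assert_allclose(
            minus.coords, pca.mean_coordinates - disp, atol=1e-12
        )

    def test_displacement_concentrated_on_dom2(
        self, clamshell_pca, clamshell_dataset, clamshell_model
    ):
        ct, _, _, _ = clamshell_dataset
        _, pca = clamshell_pca
        v = pca.eigenvectors[0].reshape(-1, 3)
        norms = np.sum(v**2, axis=1)
        pos = {int(a): i for i, a in enumerate(pca.atom_indices)}
        dom2 = [pos[int(i)] for i in clamshell_model.dom2.atom_indices if int(i) in pos]
        dom1 = [pos[int(i)] for i in clamshell_model.dom1.atom_indices if int(i) in pos]
        assert norms[dom2].sum() > 10 * norms[dom1].sum()

    def test_roundtrip_via_pdb(self, clamshell_pca, clamshell_dataset):
        ct, _, _, _ = clamshell_dataset
        _, pca = clamshell_pca
        text = write_mode_arrows_pdb(pca, ct.trajectory.topology, 0, 0.5)
        traj = read_pdb_trajectory(text)
        assert traj.n_frames == 2
        disp = 0.5 * pca.eigenvectors[0].reshape(-1, 3)
        np.testing.assert_allclose(
            traj.frames[0] - traj.frames[1], 2 * disp, atol=2e-4
        )

    def test_bad_scale(self, clamshell_pca, clamshell_dataset):
        ct, _, _, _ = clamshell_dataset
        _, pca = clamshell_pca
        with pytest.raises(ValueError, match="positive"):
            export_mode_arrows(pca, ct.trajectory.topology, 0, 0.0)


class TestSerialization:
    def test_roundtrip(self, clamshell_pca):
        _, pca = clamshell_pca
        again = read_pca(write_pca(pca))
        np.testing.assert_allclose(again.eigenvalues, pca.eigenvalues, rtol=1e-8)
        np.testing.assert_allclose(again.eigenvectors, pca.eigenvectors, atol=1e-8)
        np.testing.assert_allclose(
            again.mean_coordinates, pca.mean_coordinates, atol=1e-8
        )
        assert again.mode_labels == pca.mode_labels
        np.testing.assert_array_equal(again.atom_indices, pca.atom_indices)
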