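"""Trajectory fitting, RMSF, PCA/projection, clustering, distances, FMA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from resdyn import ensemble as ens
from resdyn import synthetic as syn


@pytest.fixture(scope="module")
def base():
    st, _ = syn.make_toy_complex(seed=1, n_residues=12)
    return st


def _rigid_copies(base, n, seed=0):
    rng = np.random.default_rng(seed)
    frames = np.empty((n, len(base), 3))
    for t in range(n):
        R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        frames[t] = base.coords @ R.T + rng.normal(0, 10, 3)
    return ens.Trajectory(base, frames)


class TestFitFrames:
    def test_rigid_body_motion_removed_exactly(self, base):
        traj = _rigid_copies(base, 8)
        fitted = ens.fit_frames(traj, base.coords, "name N,CA,C,O")
        assert np.abs(fitted.coords - base.coords).max() < 1e-6

    def test_idempotent_on_fitted_trajectory(self, base):
        traj = _rigid_copies(base, 6)
        once = ens.fit_frames(traj, base.coords, None)
        twice = ens.fit_frames(once, base.coords, None)
        np.testing.assert_allclose(once.coords, twice.coords, atol=1e-9)

    def test_planted_mode_mean_recovers_base(self, base):
        modes = syn.random_orthonormal_modes(len(base), 2, seed=9)
        traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
            base, modes, np.array([0.5, 0.2]), n_frames=4000, seed=9,
            rigid_jitter=(0.1, 2.0)))
        fitted = ens.fit_frames(traj, base.coords, "name N,CA,C,O")
        # per-coordinate amplitude SD ~ sqrt(0.7/3N); mean over 4000 frames
        err = np.abs(fitted.coords.mean(axis=0) - base.coords).max()
        assert err < 0.05

    def test_degenerate_selection_rejected(self, base):
        traj = _rigid_copies(base, 3)
        with pytest.raises(Exception):
            ens.fit_frames(traj, base.coords, np.array([0, 1]))


class TestRMSF:
    def test_frozen_trajectory_zero(self, base):
        traj = ens.Trajectory(base, np.repeat(base.coords[None], 10, axis=0))
        prof = ens.rmsf_profile(traj, "name CA")
        np.testing.assert_allclose(prof.rmsf, 0.0)

    def test_isotropic_jitter_gives_sigma_sqrt3(self, base):
        sigma = 0.3
        traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
            base, noise_sd=sigma, n_frames=10000, seed=21))
        prof = ens.rmsf_profile(traj, "name CA")
        assert prof.rmsf.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.02)

    def test_region_with_doubled_jitter_doubles_mean(self, base):
        rng = np.random.default_rng(3)
        ca = base.select("chain A & name CA")
        resnums = np.array([base.atoms[i].residue_number for i in ca])
        hot = ca[(resnums >= 164) & (resnums <= 169)]
        T = 8000
        frames = np.repeat(base.coords[None], T, axis=0)
        frames += rng.normal(0, 0.2, frames.shape)
        frames[:, hot, :] = np.repeat(base.coords[None], T, axis=0)[:, hot, :] \
            + rng.normal(0, 0.4, (T, hot.size, 3))
        prof = ens.rmsf_profile(ens.Trajectory(base, frames), ca,
                                region=(164, 169))
        background = prof.rmsf[resnums < 164].mean()
        assert prof.region_mean == pytest.approx(2 * background, rel=0.05)
        assert prof.region_se > 0

    def test_single_frame_warns_and_returns_zero(self, base):
        traj = ens.Trajectory(base, base.coords[None])
        with pytest.warns(UserWarning):
            prof = ens.rmsf_profile(traj, "name CA")
        np.testing.assert_allclose(prof.rmsf, 0.0)


class TestPCA:
    def test_single_axis_motion_single_mode(self, base):
        T = 50
        frames = np.repeat(base.coords[None], T, axis=0)
        frames[:, 0, 0] += np.linspace(-1, 1, T)  # one coordinate varies
        model = ens.pca_decompose(ens.Trajectory(base, frames))
        assert model.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_planted_variances_4_to_1(self, base):
        modes = syn.random_orthonormal_modes(len(base), 2, seed=5)
        traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
            base, modes, np.array([4.0, 1.0]), n_frames=5000, seed=2))
        model = ens.pca_decompose(traj)
        assert model.variance_fractions[0] == pytest.approx(0.8, abs=0.02)
        assert model.variance_fractions[1] == pytest.approx(0.2, abs=0.02)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_planted_spectrum_43_41_8_3_2_recovered(self, base, seed):
        """Variance fractions of a planted 43:41:8:3:2 spectrum come back
        within 2 percentage points at T=5000."""
        v = np.array([43.0, 41.0, 8.0, 3.0, 2.0])
        v /= v.sum()
        modes = syn.random_orthonormal_modes(len(base), 5, seed=seed)
        traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
            base, modes, v, n_frames=5000, seed=seed))
        model = ens.pca_decompose(traj)
        np.testing.assert_allclose(model.variance_fractions[:5], v, atol=0.02)

    def test_eigenvalue_sum_equals_total_variance(self, base):
        traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
            base, noise_sd=0.2, n_frames=200, seed=8))
        model = ens.pca_decompose(traj, "name N,CA,C,O")
        assert model.eigenvalues.sum() == pytest.approx(model.total_variance,
                                                        rel=1e-8)
        G = model.modes.T @ model.modes
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)

    def test_fewer_than_two_frames_rejected(self, base):
        traj = ens.Trajectory(base, base.coords[None])
        with pytest.raises(ValueError):
            ens.pca_decompose(traj)


@pytest.fixture(scope="module")
def model_and_traj(base):
    modes = syn.random_orthonormal_modes(len(base), 3, seed=13)
    traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
        base, modes, np.array([2.0, 1.0, 0.5]), n_frames=2000, seed=13))
    return ens.pca_decompose(traj), traj


class TestProjection:
    def test_projection_variance_equals_eigenvalue(self, model_and_traj):
        model, traj = model_and_traj
        P = ens.project_onto_modes(traj, model, [0, 1, 2])
        np.testing.assert_allclose(P.var(axis=0), model.eigenvalues[:3],
                                   rtol=1e-8)

    def test_mean_frame_projects_to_zero(self, base, model_and_traj):
        model, traj = model_and_traj
        mean_frame = model.mean.reshape(1, -1, 3)
        t1 = ens.Trajectory(base, mean_frame)
        P = ens.project_onto_modes(t1, model, [0, 1])
        np.testing.assert_allclose(P, 0.0, atol=1e-10)

    def test_shared_mode_cross_projection(self, base):
        """A second ensemble sharing only planted mode 1 projects onto mode 1
        with the generator variance and onto mode 2 with ~nothing."""
        modes = syn.random_orthonormal_modes(len(base), 2, seed=31)
        t_ref = syn.simulate_trajectory(syn.TrajectoryRecipe(
            base, modes, np.array([3.0, 1.0]), n_frames=4000, seed=31))
        model = ens.pca_decompose(t_ref)
        t_other = syn.simulate_trajectory(syn.TrajectoryRecipe(
            base, modes[:1], np.array([2.0]), n_frames=4000, seed=77))
        P = ens.project_onto_modes(t_other, model, [0, 1])
        assert P[:, 0].var() == pytest.approx(2.0, rel=0.1)
        assert P[:, 1].var() < 0.05

    def test_missing_atoms_listed(self, base, model_and_traj):
        model, _ = model_and_traj
        sub, _ = syn.make_toy_complex(seed=1, n_residues=5)
        t_sub = ens.Trajectory(sub, sub.coords[None].repeat(3, axis=0))
        with pytest.raises(ens.AtomMappingError):
            ens.project_onto_modes(t_sub, model)

    def test_common_atom_model_accepts_truncated_construct(self, base):
        """An N-terminally truncated construct projects cleanly onto a model
        built on the shared residue range (the cross-construct protocol)."""
        common = base.select("resi 164-169 & name N,CA,C,O")
        modes = syn.random_orthonormal_modes(len(base), 1, seed=41)
        traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
            base, modes, np.array([1.0]), n_frames=500, seed=41))
        model = ens.pca_decompose(traj, common)
        sub, _ = syn.make_toy_complex(seed=1, n_residues=12)
        t2 = syn.simulate_trajectory(syn.TrajectoryRecipe(
            sub, n_frames=50, seed=42, noise_sd=0.1))
        P = ens.project_onto_modes(t2, model)
        assert P.shape == (50, model.modes.shape[1])


class TestJarvisPatrick:
    def test_identical_frames_one_cluster(self, base):
        traj = ens.Trajectory(base, np.repeat(base.coords[None], 15, axis=0))
        res = ens.jarvis_patrick_cluster(traj, None, 2.0, 10)
        assert res.n_clusters == 1
        assert res.sizes[0] == 15

    def test_two_conformational_bundles_two_clusters(self, base):
        rng = np.random.default_rng(7)
        conf_a = base.coords.copy()
        conf_b = base.coords.copy()
        conf_b[: len(base) // 2] += 8.0  # internal deformation, not rigid
        frames = []
        for conf in (conf_a, conf_b):
            for _ in range(12):
                frames.append(conf + rng.normal(0, 0.05, conf.shape))
        res = ens.jarvis_patrick_cluster(
            ens.Trajectory(base, np.array(frames)), None, 2.0, 10)
        assert res.n_clusters == 2
        assert sorted(res.sizes.tolist()) == [12, 12]

    def test_partition_invariant_under_frame_permutation(self, base):
        rng = np.random.default_rng(17)
        conf_b = base.coords + np.where(
            (np.arange(len(base)) % 2 == 0)[:, None], 6.0, 0.0)
        frames = np.array(
            [base.coords + rng.normal(0, 0.05, base.coords.shape) for _ in range(8)]
            + [conf_b + rng.normal(0, 0.05, base.coords.shape) for _ in range(8)]
        )
        traj = ens.Trajectory(base, frames)
        res = ens.jarvis_patrick_cluster(traj, None, 2.0, 5)
        perm = rng.permutation(16)
        res_p = ens.jarvis_patrick_cluster(
            ens.Trajectory(base, frames[perm]), None, 2.0, 5)
        # same partition up to relabeling
        for i in range(16):
            for j in range(16):
                same = res.labels[i] == res.labels[j]
                same_p = res_p.labels[np.argsort(perm)[i]] == \
                    res_p.labels[np.argsort(perm)[j]]
                assert same == same_p

    def test_invariant_under_global_rigid_motion(self, base):
        rng = np.random.default_rng(23)
        frames = np.array(
            [base.coords + rng.normal(0, 0.1, base.coords.shape) for _ in range(12)])
        res1 = ens.jarvis_patrick_cluster(ens.Trajectory(base, frames), None, 2.0, 8)
        R = Rotation.from_rotvec([0.4, -0.2, 0.9]).as_matrix()
        moved = np.array([f @ R.T + [30.0, -12.0, 5.0] for f in frames])
        res2 = ens.jarvis_patrick_cluster(ens.Trajectory(base, moved), None, 2.0, 8)
        np.testing.assert_array_equal(res1.labels, res2.labels)

    def test_occupancy_table_ordered(self, base):
        rng = np.random.default_rng(29)
        conf_b = base.coords + np.where(
            (np.arange(len(base)) % 3 == 0)[:, None], 7.0, 0.0)
        frames = np.array(
            [base.coords + rng.normal(0, 0.05, base.coords.shape) for _ in range(10)]
            + [conf_b + rng.normal(0, 0.05, base.coords.shape) for _ in range(5)]
        )
        res = ens.jarvis_patrick_cluster(ens.Trajectory(base, frames), None, 2.0, 3)
        tab = res.occupancy_table()
        assert list(tab["size"]) == sorted(tab["size"], reverse=True)
        assert res.labels[res.representatives[0]] == 0


class TestDistanceSeries:
    def test_static_pair_constant(self, base):
        traj = ens.Trajectory(base, np.repeat(base.coords[None], 5, axis=0))
        s, lo, hi = ens.distance_series(traj, 0, 1)
        assert lo == hi == pytest.approx(s[0])

    def test_planted_oscillation_min_max(self, base):
        i = int(base.select("chain A & name CA")[0])
        j = int(base.select("chain E & name P")[0])
        T = 40
        frames = np.repeat(base.coords[None], T, axis=0)
        direction = frames[0, j] - frames[0, i]
        direction /= np.linalg.norm(direction)
        for t in range(T):
            d = 18.0 if t % 2 else 32.0
            frames[t, j] = frames[t, i] + d * direction
        traj = ens.Trajectory(base, frames)
        s, lo, hi = ens.distance_series(traj, i, j)
        assert (lo, hi) == (pytest.approx(18.0), pytest.approx(32.0))

    def test_minimum_image_across_boundary(self, base):
        frames = np.repeat(base.coords[None], 2, axis=0)
        frames[:, 0] = [1.0, 5.0, 5.0]
        frames[:, 1] = [47.0, 5.0, 5.0]  # true separation 4 under box 50
        traj = ens.Trajectory(base, frames, box=np.full((2, 3), 50.0))
        s, lo, hi = ens.distance_series(traj, 0, 1)
        assert lo == hi == pytest.approx(4.0)


@pytest.fixture(scope="module")
def projections(base):
    modes = syn.random_orthonormal_modes(len(base), 5, seed=55)
    traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
        base, modes, np.array([2.5, 2.0, 1.0, 0.5, 0.25]),
        n_frames=5000, seed=55))
    model = ens.pca_decompose(traj)
    return ens.project_onto_modes(traj, model, np.arange(5))


class TestFMA:
    def test_exact_single_mode_recovery(self, projections):
        obs = projections[:, 2].copy()
        fma = ens.functional_mode_analysis(projections, obs)
        assert fma.beta[2] == pytest.approx(1.0, abs=1e-8)
        others = np.delete(fma.beta, 2)
        assert np.abs(others).max() < 1e-8
        assert fma.r_train == pytest.approx(1.0, abs=1e-9)

    def test_planted_linear_model_recovered(self, projections, rng):
        obs = 0.6 * projections[:, 0] + 0.8 * projections[:, 1]
        noise = rng.normal(0, 0.05 * obs.std(), obs.size)
        fma = ens.functional_mode_analysis(projections, obs + noise)
        assert fma.beta[0] == pytest.approx(0.6, rel=0.05)
        assert fma.beta[1] == pytest.approx(0.8, rel=0.05)
        assert fma.r_train > 0.99 and fma.r_valid > 0.99

    def test_independent_observable_has_no_validation_power(self, projections, rng):
        obs = rng.normal(size=projections.shape[0])
        fma = ens.functional_mode_analysis(projections, obs)
        assert abs(fma.r_valid) < 0.1

    def test_constant_observable_rejected(self, projections):
        with pytest.raises(ens.ConstantObservableError):
            ens.functional_mode_analysis(projections,
                                         np.ones(projections.shape[0]))

    def test_composite_mode_vector_is_beta_combination(self, base, projections):
        modes = syn.random_orthonormal_modes(len(base), 5, seed=55)
        traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
            base, modes, np.array([2.5, 2.0, 1.0, 0.5, 0.25]),
            n_frames=200, seed=55))
        model = ens.pca_decompose(traj, n_modes=5)
        P = ens.project_onto_modes(traj, model, np.arange(5))
        fma = ens.functional_mode_analysis(P, P[:, 0] + 0.5 * P[:, 1],
                                           model=model)
        expected = model.modes[:, :5] @ fma.beta
        np.testing.assert_allclose(fma.mode_vector, expected, atol=1e-12)


class TestTrajectoryContainer:
    def test_unit_conversion_roundtrip(self, base):
        traj = ens.Trajectory(base, base.coords[None].repeat(3, axis=0))
        nm = traj.in_units("nm")
        assert nm.units == "nm"
        np.testing.assert_allclose(nm.coords * 10.0, traj.coords)
        back = nm.in_units("angstrom")
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-12)

    def test_mode_extreme_structures_span_amplitude(self, base, tmp_path):
        modes = syn.random_orthonormal_modes(len(base), 2, seed=5)
        traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
            base, modes, np.array([4.0, 1.0]), n_frames=100, seed=2))
        model = ens.pca_decompose(traj)
        p = tmp_path / "extremes.pdb"
        ens.write_mode_extremes(model, base, mode=0, amplitude=3.0, path=p)
        t = ens.read_trajectory(p)
        assert t.n_frames == 2
        # the two extremes differ by 2 x amplitude along a unit mode
        disp = np.linalg.norm(t.coords[0] - t.coords[1])
        assert disp == pytest.approx(6.0, abs=0.01)

    def test_multimodel_pdb_roundtrip(self, base, tmp_path):
        traj = syn.simulate_trajectory(syn.TrajectoryRecipe(
            base, noise_sd=0.3, n_frames=4, seed=2))
        p = tmp_path / "traj.pdb"
        ens.write_multimodel_pdb(traj, p)
        back = ens.read_trajectory(p)
        assert back.n_frames == 4
        assert back.n_atoms == len(base)
        np.testing.assert_allclose(back.coords, traj.coords, atol=5e-4)
        assert [a.key for a in back.topology.atoms] == \
            [a.key for a in base.atoms]
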