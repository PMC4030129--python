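import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr

from enmdyn import (
    Trajectory,
    anm_hessian,
    build_network,
    cluster_select,
    compute_modes,
    covariance_pca,
    eda_bfactors,
    eda_dccm,
    nma_bfactors,
    overlap,
    superpose,
)
from enmdyn.eda import PCAResult
from enmdyn.exceptions import (
    DegenerateSelectionError,
    ParameterError,
    UnsuperposedTrajectoryError,
)
from enmdyn.synthetic import sample_anm_ensemble


@pytest.fixture(scope="module")
def helix_modes(helix20):
    net = build_network(helix20, r_c=10.0)
    return helix20, compute_modes(anm_hessian(net))


def synthetic_traj(frames, **kw):
    return Trajectory(frames=np.asarray(frames, dtype=float), **kw)


class TestSuperpose:
    def test_exact_recovery_of_rigid_transforms(self, helix20):
        rng = np.random.default_rng(0)
        frames = []
        for _ in range(4):
            rot = Rotation.from_rotvec(rng.normal(size=3))
            frames.append(rot.apply(helix20.coords) + rng.normal(size=3) * 8)
        fitted = superpose(synthetic_traj(frames), helix20.coords)
        assert np.max(np.abs(fitted.frames - helix20.coords)) < 1e-6
        assert fitted.superposed

    def test_idempotent_on_aligned_input(self, helix20):
        rng = np.random.default_rng(1)
        frames = helix20.coords + rng.normal(scale=0.05, size=(3, 20, 3))
        once = superpose(synthetic_traj(frames), helix20.coords)
        twice = superpose(once, helix20.coords)
        assert np.max(np.abs(once.frames - twice.frames)) < 1e-8

    def test_reflection_never_applied(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=(4, 3)) * 5
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        fitted = superpose(synthetic_traj([mirrored]), ref)
        rmsd = np.sqrt(np.mean(np.sum((fitted.frames[0] - ref) ** 2, axis=1)))
        assert rmsd > 1e-3
        # brute-force search over proper rotations cannot do better
        best = np.inf
        for _ in range(3000):
            rot = Rotation.from_rotvec(rng.normal(size=3) * np.pi)
            cand = rot.apply(mirrored - mirrored.mean(0)) + ref.mean(0)
            best = min(best, np.sqrt(np.mean(
                np.sum((cand - ref) ** 2, axis=1))))
        assert rmsd <= best + 1e-6

    def test_small_or_collinear_selection_rejected(self, helix20):
        traj = synthetic_traj([helix20.coords])
        with pytest.raises(DegenerateSelectionError):
            superpose(traj, helix20.coords, fit_selection=[0, 1])
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateSelectionError):
            superpose(synthetic_traj([line]), line)


class TestCovariancePca:
    def test_requires_superposed_trajectory(self, helix20):
        traj = synthetic_traj([helix20.coords, helix20.coords])
        with pytest.raises(UnsuperposedTrajectoryError):
            covariance_pca(traj)

    def test_constant_trajectory_has_zero_variance(self, helix20):
        traj = synthetic_traj([helix20.coords] * 5, superposed=True)
        pca = covariance_pca(traj, burn_in_fraction=0.0)
        assert np.all(pca.modes.eigenvalues == 0.0)

    def test_variance_conservation(self, helix20):
        rng = np.random.default_rng(4)
        frames = helix20.coords + rng.normal(scale=0.3, size=(50, 20, 3))
        pca = covariance_pca(synthetic_traj(frames, superposed=True),
                             burn_in_fraction=0.0)
        x = frames.reshape(50, -1)
        total = np.mean(np.sum((x - x.mean(0)) ** 2, axis=1))
        assert pca.modes.eigenvalues.sum() == pytest.approx(total, rel=1e-8)

    def test_burn_in_discards_leading_frames(self, helix20):
        frames = np.tile(helix20.coords, (30, 1, 1))
        pca = covariance_pca(synthetic_traj(frames, superposed=True),
                             burn_in_fraction=1.0 / 6.0)
        assert pca.frames_used[0] == 5 and len(pca.frames_used) == 25

    def test_single_mode_ensemble_recovered(self, helix_modes):
        helix, modes = helix_modes
        traj = sample_anm_ensemble(modes, helix.coords, temperature=298.0,
                                   n_frames=5000, k_list=[1], seed=9)
        pca = covariance_pca(traj, burn_in_fraction=0.0)
        o = overlap(modes.mode_displacements(1),
                    pca.modes.mode_displacements(1))
        assert o >= 0.99

    def test_projection_of_mean_is_zero(self, helix20):
        rng = np.random.default_rng(6)
        frames = helix20.coords + rng.normal(scale=0.2, size=(40, 20, 3))
        pca = covariance_pca(synthetic_traj(frames, superposed=True),
                             burn_in_fraction=0.0)
        assert np.abs(pca.projections.mean(axis=0)).max() < 1e-10


class TestClusterSelect:
    def _pca_from_projections(self, proj, helix20):
        n, k = proj.shape
        frames = np.tile(helix20.coords, (n, 1, 1))
        modes = covariance_pca(
            synthetic_traj(frames, superposed=True),
            burn_in_fraction=0.0).modes
        return PCAResult(mean_coords=helix20.coords, modes=modes,
                         projections=np.column_stack(
                             [proj, np.zeros((n, 60 - k))]),
                         frames_used=np.arange(n))

    def test_unimodal_cloud_is_one_dominant_cluster(self, helix20):
        rng = np.random.default_rng(11)
        proj = rng.normal(size=(10000, 3))
        sel = cluster_select(self._pca_from_projections(proj, helix20))
        labels = sel.cluster_labels
        assert (labels == sel.selected_cluster).mean() >= 0.95

    def test_dense_cluster_beats_large_diffuse_one(self, helix20):
        rng = np.random.default_rng(12)
        tight = rng.normal(scale=0.05, size=(300, 3))
        broad = rng.normal(scale=1.0, size=(600, 3)) + 8.0
        proj = np.vstack([tight, broad])
        sel = cluster_select(self._pca_from_projections(proj, helix20),
                             grid_bins=12)
        chosen = np.flatnonzero(sel.cluster_labels == sel.selected_cluster)
        assert set(chosen) <= set(range(300))
        assert sel.n_selected == 300

    def test_identical_frames_trivially_selected(self, helix20):
        proj = np.zeros((20, 3))
        sel = cluster_select(self._pca_from_projections(proj, helix20))
        assert sel.n_selected == 20
        assert np.isinf(sel.density_score)

    def test_too_few_frames_rejected(self, helix20):
        proj = np.zeros((5, 3))
        with pytest.raises(ParameterError):
            cluster_select(self._pca_from_projections(proj, helix20))

    def test_permutation_invariant_selection(self, helix20):
        rng = np.random.default_rng(13)
        tight = rng.normal(scale=0.1, size=(200, 3))
        broad = rng.normal(scale=1.5, size=(300, 3)) + 6.0
        proj = np.vstack([tight, broad])
        sel1 = cluster_select(self._pca_from_projections(proj, helix20))
        perm = rng.permutation(len(proj))
        sel2 = cluster_select(
            self._pca_from_projections(proj[perm], helix20))
        f1 = set(sel1.frame_indices.tolist())
        f2 = {int(perm[i]) for i in sel2.frame_indices}
        assert f1 == f2


class TestTrajectoryDccmBfactors:
    def test_opposite_translation_fully_anticorrelated(self):
        base = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        frames = [base + np.array([[s, 0, 0], [-s, 0, 0]])
                  for s in np.sin(np.linspace(0, 6 * np.pi, 60))]
        cc = eda_dccm(synthetic_traj(frames, superposed=True),
                      mode_list=None).matrix
        assert cc[0, 1] == pytest.approx(-1.0)

    def test_independent_beads_uncorrelated(self):
        rng = np.random.default_rng(14)
        frames = rng.normal(size=(10000, 20, 3))
        cc = eda_dccm(synthetic_traj(frames, superposed=True),
                      mode_list=None).matrix
        off = cc[~np.eye(20, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_full_rank_reconstruction_equals_raw(self, helix20):
        rng = np.random.default_rng(15)
        frames = helix20.coords + rng.normal(scale=0.2, size=(200, 20, 3))
        traj = synthetic_traj(frames, superposed=True)
        raw = eda_dccm(traj, mode_list=None).matrix
        pca = covariance_pca(traj, burn_in_fraction=0.0)
        recon = eda_dccm(pca, mode_list=None).matrix
        np.testing.assert_allclose(recon, raw, atol=1e-8)

    def test_constant_trajectory_zero_bfactors(self, helix20):
        traj = synthetic_traj([helix20.coords] * 4, superposed=True)
        assert np.all(eda_bfactors(traj).values == 0.0)

    def test_amplitude_doubling_quadruples_bfactors(self, helix20):
        rng = np.random.default_rng(16)
        disp = rng.normal(size=(100, 20, 3))
        b1 = eda_bfactors(synthetic_traj(helix20.coords + disp,
                                         superposed=True)).values
        b2 = eda_bfactors(synthetic_traj(helix20.coords + 2 * disp,
                                         superposed=True)).values
        np.testing.assert_allclose(b2, 4.0 * b1, rtol=1e-10)

    def test_ensemble_bfactors_consistent_with_modes(self, helix_modes):
        helix, modes = helix_modes
        traj = sample_anm_ensemble(modes, helix.coords, temperature=298.0,
                                   n_frames=5000, seed=17)
        b_traj = eda_bfactors(traj).values
        b_nma = nma_bfactors(modes, temperature=298.0).values
        assert pearsonr(b_traj, b_nma)[0] >= 0.95

    def test_dccm_invariant_to_global_rotation_before_fit(self, helix_modes):
        helix, modes = helix_modes
        traj = sample_anm_ensemble(modes, helix.coords, temperature=298.0,
                                   n_frames=400, k_list=[1, 2], seed=18)
        cc0 = eda_dccm(traj, mode_list=None).matrix
        rot = Rotation.from_rotvec([0.4, 0.2, -0.9])
        rotated = Trajectory(frames=rot.apply(
            traj.frames.reshape(-1, 3)).reshape(traj.frames.shape))
        fitted = superpose(rotated, helix.coords)
        cc1 = eda_dccm(fitted, mode_list=None).matrix
        np.testing.assert_allclose(cc1, cc0, atol=5e-3)
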