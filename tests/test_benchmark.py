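from itertools import combinations

import numpy as np
import pytest
from scipy.stats import spearmanr

from conformotion.benchmark import (KernelSpec, cluster_for_cv, hull_distance,
                                    interpolate_states, kernel_matrix, kpca_fit,
                                    kpca_inverse, kpca_project,
                                    leave_one_cluster_out,
                                    median_pairwise_distance,
                                    normalized_hull_distance)
from conformotion.motions import decompose, project


def _hull_oracle(p, T):
    """Exact distance to the hull by enumerating all faces (subsets)."""
    best = np.inf
    n = len(T)
    for k in range(1, n + 1):
        for S in combinations(range(n), k):
            Ts = T[list(S)]
            A = np.zeros((k + 1, k + 1))
            A[:k, :k] = 2 * Ts @ Ts.T
            A[:k, k] = 1.0
            A[k, :k] = 1.0
            b = np.concatenate([2 * Ts @ p, [1.0]])
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            theta = sol[:k]
            if (theta >= -1e-12).all():
                best = min(best, np.linalg.norm(theta @ Ts - p))
    return best


class TestKernels:
    def test_rbf_self_similarity_is_one(self, rng):
        R = rng.normal(size=(4, 9))
        K = kernel_matrix(R, R, KernelSpec("rbf", sigma=2.0))
        assert np.allclose(np.diag(K), 1.0)

    def test_polynomial_large_sigma_limit(self, rng):
        R = rng.normal(size=(3, 6))
        K = kernel_matrix(R, R, KernelSpec("polynomial", sigma=1e8))
        assert np.allclose(K, 1.0, atol=1e-6)   # (0 + c)^d with c=1, d=3

    def test_rbf_kernel_matrix_is_psd(self, rng):
        R = rng.normal(size=(5, 12))
        K = kernel_matrix(R, R, KernelSpec("rbf", sigma=3.0))
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-10

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("rbf", sigma=0.0)
        with pytest.raises(ValueError):
            KernelSpec("laplacian", sigma=1.0)
        with pytest.raises(ValueError):
            kernel_matrix(np.ones((2, 3)), np.full((2, 3), np.nan),
                          KernelSpec("rbf", sigma=1.0))


class TestKpca:
    def test_large_sigma_matches_linear_pca_projections(self, linear_small):
        ens, truth, dense = linear_small
        spec = KernelSpec("rbf", sigma=100 * median_pairwise_distance(dense))
        model = kpca_fit(dense, spec, n_components=1)
        pk = kpca_project(model, dense)[:, 0]
        dec = decompose(dense)
        pl = np.array([project(dec, r, 1)[0] for r in dense])
        assert abs(np.corrcoef(pk, pl)[0, 1]) > 0.999

    def test_duplicate_rows_get_identical_projections(self, rng):
        R = rng.normal(size=(6, 9))
        R[3] = R[1]
        model = kpca_fit(R, KernelSpec("rbf", sigma=3.0), n_components=2)
        P = kpca_project(model, R)
        assert np.allclose(P[1], P[3], atol=1e-10)

    def test_projections_match_explicit_eigendecomposition(self, rng):
        """Oracle: double-centered kernel matrix eigensolver."""
        R = rng.normal(size=(7, 12))
        spec = KernelSpec("rbf", sigma=4.0)
        model = kpca_fit(R, spec, n_components=3)
        P = kpca_project(model, R)
        K = kernel_matrix(R, R, spec)
        n = len(K)
        H = np.eye(n) - np.ones((n, n)) / n
        Kc = H @ K @ H
        evals, evecs = np.linalg.eigh(Kc)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        expected = evecs[:, :3] * np.sqrt(evals[:3])
        for j in range(3):
            assert np.allclose(np.abs(P[:, j]), np.abs(expected[:, j]),
                               atol=1e-8)

    def test_training_point_projects_to_training_projection(self, rng):
        R = rng.normal(size=(6, 9))
        model = kpca_fit(R, KernelSpec("polynomial", sigma=3.0), n_components=2)
        P_train = model.training_projections
        assert np.allclose(kpca_project(model, R[2]), P_train[2], atol=1e-10)

    def test_preimage_interpolation_limit(self, linear_small):
        ens, truth, dense = linear_small
        spec = KernelSpec("rbf", sigma=median_pairwise_distance(dense))
        model = kpca_fit(dense, spec, n_components=5, preimage_alpha=1e-12)
        recon = kpca_inverse(model, kpca_project(model, dense[3]))
        assert np.linalg.norm(recon - dense[3]) / np.sqrt(ens.m) < 1e-3

    def test_preimage_large_alpha_shrinks_prediction(self, linear_small):
        """Ridge limit: with huge regularization the (intercept-free)
        pre-image regressor shrinks its prediction toward zero."""
        ens, truth, dense = linear_small
        spec = KernelSpec("rbf", sigma=median_pairwise_distance(dense))
        model = kpca_fit(dense, spec, n_components=2, preimage_alpha=1e8)
        recon = kpca_inverse(model, kpca_project(model, dense[0]))
        assert np.linalg.norm(recon) < 1e-3 * np.linalg.norm(dense[0])

    def test_alpha_must_be_positive(self, rng):
        with pytest.raises(ValueError):
            kpca_fit(rng.normal(size=(4, 6)), KernelSpec("rbf", sigma=1.0),
                     preimage_alpha=0.0)

    def test_kpca_beats_pca_on_curved_manifold(self, arc_fixture):
        """With a 1-component budget, the kernel model captures the arc's
        curvature that the linear model cannot (oracle: linear PCA on the
        same folds)."""
        ens, truth, dense = arc_fixture
        pca = leave_one_cluster_out(dense, ens.m, "pca", seed=0, l=1)
        spec = KernelSpec("rbf", sigma=2 * median_pairwise_distance(dense))
        kpca = leave_one_cluster_out(dense, ens.m, "kpca", spec, alpha=1e-8,
                                     seed=0, l=1)
        assert kpca.summary["mean_rmsd"] < pca.summary["mean_rmsd"]


class TestHullDistance:
    def test_interior_point_is_zero(self):
        T = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        assert hull_distance(np.array([1.0, 1.0]), T) == pytest.approx(0.0,
                                                                       abs=1e-8)

    def test_one_dimensional_arithmetic(self):
        T = np.array([[0.0], [3.0]])
        assert hull_distance(np.array([5.0]), T) == pytest.approx(2.0)
        assert normalized_hull_distance(np.array([5.0]), T, 4) == \
            pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            T = rng.normal(size=(6, 2)) * 3
            p = rng.normal(size=2) * 4
            assert hull_distance(p, T) == pytest.approx(_hull_oracle(p, T),
                                                        abs=1e-8)

    def test_training_points_and_combinations_inside(self, rng):
        T = rng.normal(size=(5, 3))
        for t in T:
            assert hull_distance(t, T) < 1e-8
        theta = rng.dirichlet(np.ones(5))
        assert hull_distance(theta @ T, T) < 1e-8

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            hull_distance(np.array([1.0]), np.empty((0, 1)))


class TestCvClustering:
    def test_k_equals_l_plus_two(self, linear_small):
        ens, truth, dense = linear_small
        dec = decompose(dense)
        labels, l = cluster_for_cv(dec, dense, seed=0)
        assert l == 1
        assert len(np.unique(labels)) == 3

    def test_separated_blobs_recovered(self, rng):
        """Three well-separated 1D blobs embedded in coordinate space."""
        direction = rng.normal(size=12)
        direction /= np.linalg.norm(direction)
        amps = np.concatenate([rng.normal(0, 0.1, 6),
                               rng.normal(20, 0.1, 6),
                               rng.normal(40, 0.1, 6)])
        R = amps[:, None] * direction[None, :]
        dec = decompose(R)
        labels, l = cluster_for_cv(dec, R, seed=0)
        assert l == 1
        blocks = [set(labels[:6]), set(labels[6:12]), set(labels[12:])]
        assert all(len(b) == 1 for b in blocks)
        assert len(set.union(*blocks)) == 3

    def test_deterministic_with_seed(self, arc_fixture):
        ens, truth, dense = arc_fixture
        dec = decompose(dense)
        l1, _ = cluster_for_cv(dec, dense, seed=42)
        l2, _ = cluster_for_cv(dec, dense, seed=42)
        assert np.array_equal(l1, l2)

    def test_too_few_conformations_rejected(self, rng):
        R = rng.normal(size=(2, 9))
        dec = decompose(R)
        with pytest.raises(ValueError):
            cluster_for_cv(dec, R)


class TestLeaveOneClusterOut:
    def test_every_conformation_tested_once(self, arc_fixture):
        ens, truth, dense = arc_fixture
        report = leave_one_cluster_out(dense, ens.m, "pca", seed=0)
        assert sorted(report.records["index"]) == list(range(ens.n))

    def test_in_span_conformation_reconstructed_exactly(self, rng):
        """A held-out point inside the training linear span has ~0 error."""
        direction = rng.normal(size=15)
        direction /= np.linalg.norm(direction)
        amps = np.linspace(-5, 5, 12)
        R = amps[:, None] * direction[None, :]
        labels = np.zeros(12, dtype=int)
        labels[5] = 1    # interior point as its own cluster
        report = leave_one_cluster_out(R, 5, "pca", labels=labels, l=1, seed=0)
        mid = report.records[report.records["cluster"] == 1]
        assert (mid["rmsd"] < 1e-6).all()

    def test_extrapolation_error_grows_with_amplitude(self, arc_fixture):
        """Held-out extremes of a curved manifold are reconstructed worse
        the further they are from the training hull."""
        ens, truth, dense = arc_fixture
        report = leave_one_cluster_out(dense, ens.m, "pca", seed=0, l=1)
        rho = spearmanr(report.records["rmsd"],
                        report.records["d_norm"]).statistic
        assert rho > 0.5

    def test_summary_aggregates_records(self, arc_fixture):
        ens, truth, dense = arc_fixture
        report = leave_one_cluster_out(dense, ens.m, "pca", seed=0)
        frac = (report.records["rmsd"] < 2.0).mean()
        assert report.summary["fraction_below_2A"] == pytest.approx(frac)
        assert report.summary["n_test"] == len(report.records)


class TestInterpolation:
    def test_linear_trajectory_equidistant(self, arc_fixture):
        ens, truth, dense = arc_fixture
        dec = decompose(dense)
        labels, l = cluster_for_cv(dec, dense, seed=0)
        a, b = 0, 1
        traj = interpolate_states(dense, labels, a, b, ens.m, "pca",
                                  n_points=20, l=l)
        steps = np.linalg.norm(np.diff(traj.conformations, axis=0), axis=1)
        assert steps.std() < 1e-8 * steps.mean()
        assert len(traj.conformations) == 20

    def test_endpoints_near_cluster_centres(self, arc_fixture):
        ens, truth, dense = arc_fixture
        dec = decompose(dense)
        labels, l = cluster_for_cv(dec, dense, seed=0)
        traj = interpolate_states(dense, labels, 0, 1, ens.m, "pca",
                                  n_points=50, l=l)
        centre_a = dense[labels == 0].mean(axis=0)
        centre_b = dense[labels == 1].mean(axis=0)
        d_first = np.linalg.norm(traj.conformations[0] - centre_a)
        d_last = np.linalg.norm(traj.conformations[-1] - centre_b)
        spread = np.linalg.norm(centre_a - centre_b)
        assert d_first < 0.2 * spread and d_last < 0.2 * spread

    def test_hinge_midpoint_recovers_heldout_state(self, hinge_fixture):
        from conformotion import fill_gaps, superimpose_ensemble

        ens, truth = hinge_fixture
        ens = superimpose_ensemble(ens.subset(list(range(ens.n))))
        dense, _ = fill_gaps(ens)
        dec = decompose(dense)
        labels, l = cluster_for_cv(dec, dense, seed=0)
        proj1 = np.array([project(dec, r, 1)[0] for r in dense])
        means = {c: proj1[labels == c].mean() for c in np.unique(labels)}
        order = sorted(means, key=means.get)
        a, b = order[0], order[-1]
        held = dense[np.isin(labels, order[1:-1])]
        traj = interpolate_states(dense, labels, a, b, ens.m, "pca",
                                  n_points=50, heldout=held)
        endpoint_rmsd = np.linalg.norm(dense[labels == a].mean(0)
                                       - dense[labels == b].mean(0)) \
            / np.sqrt(ens.m)
        assert traj.min_rmsd.min() < endpoint_rmsd

    def test_identical_centres_rejected(self, rng):
        R = rng.normal(size=(8, 9))
        labels = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        R[labels == 1] = R[labels == 0]   # same centre by construction
        with pytest.raises(ValueError, match="degenerate"):
            interpolate_states(R, labels, 0, 1, 3, "pca", l=1)
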