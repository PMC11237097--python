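"""Generation benchmark: can low-dimensional representations predict
unseen conformations?

Linear PCA is the baseline; kernel PCA with RBF, polynomial and sigmoid
kernels (all parameterized by a width sigma via gamma = 1/(2 sigma^2))
is the non-linear contender, inverted through a kernel-ridge pre-image
regressor. Evaluation is leave-one-cluster-out: conformations are
k-means-clustered (k = l + 2) in the l-dimensional PCA space, each
cluster is held out in turn, and every held-out conformation is
projected, reconstructed, and scored by its RMSD to the original and by
its distance to the training set's convex hull in the representation
space (an extrapolation-difficulty proxy, reported as d / sqrt(m)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.cluster import KMeans
from sklearn.decomposition import KernelPCA
from sklearn.metrics.pairwise import polynomial_kernel, rbf_kernel, sigmoid_kernel

from .motions import MotionDecomposition, decompose, dimensionality, generate, project

DEFAULT_ALPHA = 1e-8
#: reconstruction quality cutoff in Angstrom
HIGH_QUALITY_RMSD = 2.0


@dataclass
class KernelSpec:
    """Kernel family and hyperparameters; sigma is a width in Angstrom."""

    name: str = "rbf"              # rbf | polynomial | sigmoid
    sigma: float = 1.0
    c: float = 1.0
    degree: int = 3

    def __post_init__(self):
        if self.name not in ("rbf", "polynomial", "sigmoid"):
            raise ValueError(f"unknown kernel: {self.name!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma ** 2)


@dataclass
class KernelModel:
    spec: KernelSpec
    kpca: KernelPCA
    training_R: np.ndarray
    preimage_alpha: float

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.kpca.eigenvalues_

    @property
    def training_projections(self) -> np.ndarray:
        return self.kpca.transform(self.training_R)


@dataclass
class CvReport:
    records: pd.DataFrame          # index, cluster, rmsd, d_norm, inside_hull
    method: str
    summary: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    points: np.ndarray             # n_points x l representation-space points
    conformations: np.ndarray      # n_points x 3m
    min_rmsd: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def kernel_matrix(R_a: np.ndarray, R_b: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """K_ij = k(r_i, r_j) for the rows of the two coordinate matrices."""
    R_a, R_b = np.atleast_2d(R_a), np.atleast_2d(R_b)
    if R_a.shape[1] != R_b.shape[1]:
        raise ValueError("coordinate dimensions differ")
    if not (np.isfinite(R_a).all() and np.isfinite(R_b).all()):
        raise ValueError("non-finite coordinates")
    if spec.name == "rbf":
        return rbf_kernel(R_a, R_b, gamma=spec.gamma)
    if spec.name == "polynomial":
        return polynomial_kernel(R_a, R_b, degree=spec.degree,
                                 gamma=spec.gamma, coef0=spec.c)
    return sigmoid_kernel(R_a, R_b, gamma=spec.gamma, coef0=spec.c)


def median_pairwise_distance(R: np.ndarray) -> float:
    """Robust data scale used to seed the sigma grid."""
    from scipy.spatial.distance import pdist

    d = pdist(np.atleast_2d(R))
    return float(np.median(d[d > 0])) if (d > 0).any() else 1.0


def kpca_fit(R: np.ndarray, spec: KernelSpec, n_components: Optional[int] = None,
             preimage_alpha: float = DEFAULT_ALPHA) -> KernelModel:
    """Fit kernel PCA with a kernel-ridge pre-image regressor.

    The kernel matrix is double-centered in feature space and
    eigen-decomposed; components are scaled to unit feature-space norm.
    The inverse transform is a kernel ridge regression (same kernel
    family and width) of the training coordinates on their projections,
    regularized by ``preimage_alpha``.
    """
    R = np.atleast_2d(np.asarray(R, dtype=float))
    if len(R) < 2:
        raise ValueError("kernel PCA needs at least 2 conformations")
    if preimage_alpha <= 0:
        raise ValueError("preimage_alpha must be positive")
    sk_kernel = {"rbf": "rbf", "polynomial": "poly", "sigmoid": "sigmoid"}[spec.name]
    kpca = KernelPCA(n_components=n_components, kernel=sk_kernel, gamma=spec.gamma,
                     coef0=spec.c, degree=spec.degree, fit_inverse_transform=True,
                     alpha=preimage_alpha, remove_zero_eig=(n_components is None))
    kpca.fit(R)
    return KernelModel(spec=spec, kpca=kpca, training_R=R,
                       preimage_alpha=preimage_alpha)


def kpca_project(model: KernelModel, r: np.ndarray) -> np.ndarray:
    """Project conformation(s) onto the kernel principal components."""
    r = np.asarray(r, dtype=float)
    single = r.ndim == 1
    p = model.kpca.transform(np.atleast_2d(r))
    return p[0] if single else p


def kpca_inverse(model: KernelModel, p: np.ndarray) -> np.ndarray:
    """Pre-image: map representation-space point(s) back to coordinates."""
    p = np.asarray(p, dtype=float)
    single = p.ndim == 1
    r = model.kpca.inverse_transform(np.atleast_2d(p))
    return r[0] if single else r


# ---------------------------------------------------------------------------
# distance to the training set
# ---------------------------------------------------------------------------

def hull_distance(p: np.ndarray, training_projections: np.ndarray) -> float:
    """Euclidean distance from ``p`` to the convex hull of the training
    projections (0 for interior points).

    Solves min ||sum_i theta_i t_i - p||^2 subject to theta >= 0,
    sum theta = 1: an SLSQP pass identifies the support, then the
    equality-constrained least-squares problem on that support is solved
    exactly (active-set polish), so the result matches enumeration-based
    oracles to tight tolerance in low dimension.
    """
    T = np.atleast_2d(np.asarray(training_projections, dtype=float))
    p = np.asarray(p, dtype=float).ravel()
    if T.size == 0:
        raise ValueError("empty training set")
    n = T.shape[0]
    if n == 1:
        return float(np.linalg.norm(T[0] - p))

    def objective(theta):
        d = theta @ T - p
        return float(d @ d)

    def gradient(theta):
        return 2.0 * (theta @ T - p) @ T.T

    res = minimize(objective, np.full(n, 1.0 / n), jac=gradient, method="SLSQP",
                   bounds=[(0.0, 1.0)] * n,
                   constraints=[{"type": "eq", "fun": lambda th: th.sum() - 1.0,
                                 "jac": lambda th: np.ones(n)}],
                   options={"maxiter": 1000, "ftol": 1e-16})
    theta = np.clip(res.x, 0.0, None)
    theta /= theta.sum()
    theta = _polish_support(p, T, theta)
    return float(np.linalg.norm(theta @ T - p))


def _polish_support(p: np.ndarray, T: np.ndarray, theta: np.ndarray,
                    tol: float = 1e-7) -> np.ndarray:
    """Exact equality-constrained solve on the active support."""
    support = list(np.flatnonzero(theta > tol)) or [int(np.argmax(theta))]
    for _ in range(len(T)):
        Ts = T[support]
        k = len(support)
        # KKT system of min ||Ts' th - p||^2 s.t. 1' th = 1
        A = np.zeros((k + 1, k + 1))
        A[:k, :k] = 2.0 * Ts @ Ts.T
        A[:k, k] = 1.0
        A[k, :k] = 1.0
        b = np.concatenate([2.0 * Ts @ p, [1.0]])
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        th_s = sol[:k]
        if (th_s >= -1e-10).all() or k == 1:
            th_s = np.clip(th_s, 0.0, None)
            th_s /= th_s.sum()
            candidate = np.zeros(len(T))
            candidate[support] = th_s
            old = float(np.linalg.norm(theta @ T - p))
            new = float(np.linalg.norm(candidate @ T - p))
            return candidate if new <= old + 1e-12 else theta
        support.pop(int(np.argmin(th_s)))
    return theta


def normalized_hull_distance(p: np.ndarray, training_projections: np.ndarray,
                             m: int) -> float:
    """Hull distance divided by sqrt(m), comparable to Cartesian RMSDs."""
    return hull_distance(p, training_projections) / np.sqrt(m)


# ---------------------------------------------------------------------------
# leave-one-cluster-out cross-validation
# ---------------------------------------------------------------------------

def cluster_for_cv(decomp: MotionDecomposition, R_dense: np.ndarray,
                   variance_pct: float = 90.0, seed: int = 0) -> tuple[np.ndarray, int]:
    """k-means labels in the l-dimensional PCA space, k = l + 2.

    l is the minimal number of components explaining ``variance_pct`` of
    the total positional variance.
    """
    l = max(1, dimensionality(decomp, variance_pct))
    k = l + 2
    n = len(R_dense)
    if n < k:
        raise ValueError(f"need at least {k} conformations for k-means with "
                         f"k=l+2 (l={l}); try a lower variance threshold")
    proj = np.vstack([project(decomp, r, l) for r in R_dense])
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(proj)
    return labels, l


def _pca_fold(R_train: np.ndarray, l: int):
    dec = decompose(R_train, matrix_kind="covariance", centering="mean")
    l_eff = min(l, dec.modes.shape[1])
    train_proj = np.vstack([project(dec, r, l_eff) for r in R_train])

    def proj_fn(r):
        return project(dec, r, l_eff)

    def recon_fn(p):
        return generate(dec, p, l_eff)

    return proj_fn, recon_fn, train_proj


def _kpca_fold(R_train: np.ndarray, l: int, spec: KernelSpec, alpha: float):
    l_eff = min(l, len(R_train) - 1)
    model = kpca_fit(R_train, spec, n_components=l_eff, preimage_alpha=alpha)
    train_proj = kpca_project(model, R_train)

    def proj_fn(r):
        return kpca_project(model, r)

    def recon_fn(p):
        return kpca_inverse(model, p)

    return proj_fn, recon_fn, train_proj


def leave_one_cluster_out(R_dense: np.ndarray, m: int, method: str = "pca",
                          spec: Optional[KernelSpec] = None,
                          alpha: float = DEFAULT_ALPHA,
                          variance_pct: float = 90.0, seed: int = 0,
                          labels: Optional[np.ndarray] = None,
                          l: Optional[int] = None) -> CvReport:
    """Reconstruct every conformation from a model fitted without its cluster.

    For each cluster: fit PCA or kPCA on the remaining conformations,
    project each held-out conformation, reconstruct it, and record the
    RMSD to the original plus the normalized distance to the training
    projections' convex hull. Clusters whose removal leaves fewer than 2
    training conformations are skipped with a warning.
    """
    R_dense = np.asarray(R_dense, dtype=float)
    if method not in ("pca", "kpca"):
        raise ValueError(f"unknown method: {method!r}")
    if method == "kpca" and spec is None:
        spec = KernelSpec("rbf", sigma=median_pairwise_distance(R_dense))
    full = decompose(R_dense)
    if l is None:
        l = max(1, dimensionality(full, variance_pct))
    if labels is None:
        labels, _ = cluster_for_cv(full, R_dense, variance_pct, seed)
    labels = np.asarray(labels)

    rows = []
    for cluster in np.unique(labels):
        test_idx = np.flatnonzero(labels == cluster)
        train_idx = np.flatnonzero(labels != cluster)
        if len(train_idx) < 2:
            warnings.warn(f"cluster {cluster}: fewer than 2 training "
                          "conformations left; skipped")
            continue
        if method == "pca":
            proj_fn, recon_fn, train_proj = _pca_fold(R_dense[train_idx], l)
        else:
            proj_fn, recon_fn, train_proj = _kpca_fold(R_dense[train_idx], l,
                                                       spec, alpha)
        for t in test_idx:
            p = proj_fn(R_dense[t])
            recon = recon_fn(p)
            rmsd = float(np.linalg.norm(recon - R_dense[t]) / np.sqrt(m))
            d_norm = normalized_hull_distance(p, train_proj, m)
            rows.append({"index": int(t), "cluster": int(cluster),
                         "rmsd": rmsd, "d_norm": d_norm,
                         "inside_hull": bool(d_norm < 1e-8 / np.sqrt(m))})
    records = pd.DataFrame(rows).sort_values("index").reset_index(drop=True)
    summary = {"method": method, "l": int(l),
               "n_test": int(len(records)),
               "mean_rmsd": float(records["rmsd"].mean()),
               "median_rmsd": float(records["rmsd"].median()),
               "fraction_below_2A": float((records["rmsd"] < HIGH_QUALITY_RMSD).mean())}
    if method == "kpca":
        summary.update({"kernel": spec.name, "sigma": spec.sigma, "alpha": alpha})
    return CvReport(records=records, method=method, summary=summary)


def kpca_grid_search(R_dense: np.ndarray, m: int, kernel: str = "rbf",
                     sigma_factors: Sequence[float] = (0.25, 0.5, 1, 2, 4, 8),
                     alphas: Sequence[float] = (1e-10, 1e-8, 1e-6, 1e-4, 1e-2),
                     variance_pct: float = 90.0, seed: int = 0) -> dict:
    """Log-grid over sigma (x median pairwise distance) and alpha.

    Returns the pair minimizing the mean leave-one-cluster-out RMSD, with
    folds reusing the same clustering. Selection uses the test clusters
    themselves (optimistic protocol).
    """
    scale = median_pairwise_distance(R_dense)
    full = decompose(R_dense)
    labels, l = cluster_for_cv(full, R_dense, variance_pct, seed)
    best = None
    for f in sigma_factors:
        for alpha in alphas:
            spec = KernelSpec(kernel, sigma=f * scale)
            report = leave_one_cluster_out(R_dense, m, "kpca", spec, alpha,
                                           variance_pct, seed, labels=labels, l=l)
            score = report.summary["mean_rmsd"]
            if best is None or score < best["mean_rmsd"]:
                best = {"sigma": spec.sigma, "alpha": alpha, "mean_rmsd": score}
    return best


# ---------------------------------------------------------------------------
# interpolation between states
# ---------------------------------------------------------------------------

def interpolate_states(R_dense: np.ndarray, labels: np.ndarray, cluster_a: int,
                       cluster_b: int, m: int, method: str = "pca",
                       spec: Optional[KernelSpec] = None,
                       alpha: float = DEFAULT_ALPHA, n_points: int = 50,
                       l: Optional[int] = None,
                       heldout: Optional[np.ndarray] = None) -> Trajectory:
    """Trajectory of generated conformations between two cluster centres.

    The model is fitted on the two clusters only; ``n_points`` regularly
    spaced intermediate points on the segment between the cluster centres
    in representation space are mapped back to conformations. If
    ``heldout`` conformations are given, the per-point minimum RMSD
    against them is reported.
    """
    labels = np.asarray(labels)
    idx_a = np.flatnonzero(labels == cluster_a)
    idx_b = np.flatnonzero(labels == cluster_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both clusters must be non-empty")
    union = np.concatenate([idx_a, idx_b])
    R_union = np.asarray(R_dense, dtype=float)[union]
    if l is None:
        full = decompose(R_union)
        l = max(1, dimensionality(full, 90.0))
    if method == "pca":
        proj_fn, recon_fn, _ = _pca_fold(R_union, l)
    elif method == "kpca":
        if spec is None:
            spec = KernelSpec("rbf", sigma=median_pairwise_distance(R_union))
        proj_fn, recon_fn, _ = _kpca_fold(R_union, l, spec, alpha)
    else:
        raise ValueError(f"unknown method: {method!r}")

    proj = np.vstack([proj_fn(r) for r in R_union])
    centre_a = proj[:len(idx_a)].mean(axis=0)
    centre_b = proj[len(idx_a):].mean(axis=0)
    if np.allclose(centre_a, centre_b):
        raise ValueError("cluster centres coincide: degenerate trajectory")
    t = np.arange(1, n_points + 1) / (n_points + 1)
    points = centre_a[None, :] + t[:, None] * (centre_b - centre_a)[None, :]
    conformations = np.vstack([np.asarray(recon_fn(p)).ravel() for p in points])
    min_rmsd = None
    if heldout is not None and len(heldout):
        heldout = np.atleast_2d(heldout)
        min_rmsd = np.array([min(np.linalg.norm(c - h) / np.sqrt(m) for h in heldout)
                             for c in conformations])
    return Trajectory(points=points, conformations=conformations, min_rmsd=min_rmsd)
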