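"""Linear motions of a conformational ensemble via PCA.

The n x 3m coordinate matrix (gap-filled, optionally multiplied by
per-position confidence weights) is centered on the mean or reference
conformation and decomposed by SVD — the covariance matrix is never
materialized, which matters when 3m >> n. Eigenvectors are directions of
concerted displacement ("linear motions"); eigenvalues are positional
variances. Derived statistics: intrinsic dimensionality at standard
explained-variance thresholds, entropy-based collectivity of a mode, and
RMSIP overlap between two mode subspaces.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

#: explained-variance percentages reported by default
DIM_THRESHOLDS = (50, 80, 85, 90, 95, 99)


@dataclass
class MotionDecomposition:
    modes: np.ndarray          # 3m x K, orthonormal columns, descending variance
    eigenvalues: np.ndarray    # K, non-negative
    center: np.ndarray         # 3m, in the processed (weighted) space
    matrix_kind: str           # covariance | correlation
    weights: Optional[np.ndarray]  # m-vector or None
    scale: Optional[np.ndarray]    # 3m per-coordinate std (correlation) or None
    m: int
    n: int

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def explained_fractions(self) -> np.ndarray:
        total = self.total_variance
        return self.eigenvalues / total if total > 0 else self.eigenvalues * 0.0


def _expand_weights(weights: np.ndarray) -> np.ndarray:
    return np.repeat(np.asarray(weights, dtype=float), 3)


def decompose(R_dense: np.ndarray, weights: Optional[np.ndarray] = None,
              matrix_kind: str = "covariance", centering: str = "mean",
              reference_row: Optional[int] = None) -> MotionDecomposition:
    """Eigen-decomposition of the (weighted) coordinate covariance.

    ``R_dense`` is n x 3m without NaNs. With weights, coordinates are
    multiplied by the per-position confidence before centering. With
    ``matrix_kind='correlation'`` the centered coordinates are divided by
    their standard deviation (zero-variance coordinates are excluded with
    a warning), making the decomposition scale-invariant.
    """
    R_dense = np.asarray(R_dense, dtype=float)
    n, three_m = R_dense.shape
    if n < 2:
        raise ValueError("no variance: need at least 2 conformations")
    if not np.isfinite(R_dense).all():
        raise ValueError("coordinate matrix contains non-finite values")
    X = R_dense * _expand_weights(weights) if weights is not None else R_dense.copy()
    if centering == "mean":
        center = X.mean(axis=0)
        k_max = min(n - 1, three_m)
    elif centering == "reference":
        if reference_row is None:
            raise ValueError("reference centering requires reference_row")
        center = X[reference_row].copy()
        k_max = min(n, three_m)
    else:
        raise ValueError(f"unknown centering: {centering!r}")
    Xc = X - center

    scale = None
    if matrix_kind == "correlation":
        scale = Xc.std(axis=0, ddof=1)
        dead = scale <= 1e-12
        if dead.any():
            warnings.warn(f"{int(dead.sum())} zero-variance coordinates "
                          "excluded from correlation normalization")
            scale = scale.copy()
            scale[dead] = 1.0
            Xc = Xc.copy()
            Xc[:, dead] = 0.0
        Xc = Xc / scale
    elif matrix_kind != "covariance":
        raise ValueError(f"unknown matrix kind: {matrix_kind!r}")

    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(k_max, len(s))
    eigenvalues = (s[:k] ** 2) / (n - 1)
    return MotionDecomposition(modes=vt[:k].T.copy(), eigenvalues=eigenvalues,
                               center=center, matrix_kind=matrix_kind,
                               weights=None if weights is None else np.asarray(weights, float),
                               scale=scale, m=three_m // 3, n=n)


def dimensionality(decomp: MotionDecomposition, threshold_pct: float) -> int:
    """Smallest K whose leading eigenvalues explain ``threshold_pct`` percent."""
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold must be in (0, 100]")
    fractions = decomp.explained_fractions()
    if fractions.sum() == 0:
        return 0
    cum = np.cumsum(fractions)
    return int(np.searchsorted(cum, threshold_pct / 100 - 1e-12) + 1)


def dimensionality_profile(decomp: MotionDecomposition,
                           thresholds: Sequence[int] = DIM_THRESHOLDS) -> dict[int, int]:
    return {t: dimensionality(decomp, t) for t in thresholds}


def collectivity(mode: np.ndarray, m: Optional[int] = None) -> float:
    """Degree of collectivity of a mode, in [1/m, 1].

    Per-atom squared displacements are normalized to sum to 1 and fed to
    the exponential entropy: 1 when every atom moves with the same
    magnitude, 1/m when a single atom moves.
    """
    mode = np.asarray(mode, dtype=float).reshape(-1, 3)
    if m is None:
        m = len(mode)
    u2 = (mode ** 2).sum(axis=1)
    total = u2.sum()
    if total <= 0:
        raise ValueError("zero mode vector")
    u2 = u2 / total
    nz = u2 > 0
    entropy = -(u2[nz] * np.log(u2[nz])).sum()
    return float(np.exp(entropy) / m)


def rmsip(decomp_a: MotionDecomposition, decomp_b: MotionDecomposition,
          l: int) -> float:
    """Root mean square inner product of the two leading l-mode subspaces."""
    A, B = decomp_a.modes, decomp_b.modes
    if A.shape[0] != B.shape[0]:
        raise ValueError("decompositions live in different coordinate spaces")
    if l > A.shape[1] or l > B.shape[1]:
        raise ValueError(f"l={l} exceeds available modes")
    inner = A[:, :l].T @ B[:, :l]
    return float(np.sqrt((inner ** 2).sum() / l))


def _to_processed(decomp: MotionDecomposition, conformation: np.ndarray) -> np.ndarray:
    x = np.asarray(conformation, dtype=float)
    if decomp.weights is not None:
        x = x * _expand_weights(decomp.weights)
    x = x - decomp.center
    if decomp.scale is not None:
        x = x / decomp.scale
    return x


def project(decomp: MotionDecomposition, conformation: np.ndarray,
            l: Optional[int] = None) -> np.ndarray:
    """Coordinates of a conformation in the l-dimensional mode space.

    The conformation must be superimposed into the ensemble frame (a large
    centroid offset from the centering conformation triggers a warning)
    and is weighted/scaled exactly like the training data.
    """
    l = decomp.modes.shape[1] if l is None else l
    x = np.asarray(conformation, dtype=float)
    offset = np.linalg.norm(x.reshape(-1, 3).mean(0)
                            - (decomp.center / (_expand_weights(decomp.weights)
                                                if decomp.weights is not None else 1.0)
                               ).reshape(-1, 3).mean(0))
    if offset > 100.0:
        warnings.warn("conformation centroid far from the ensemble frame; "
                      "was it superimposed?")
    return _to_processed(decomp, x) @ decomp.modes[:, :l]


def generate(decomp: MotionDecomposition, p: np.ndarray,
             l: Optional[int] = None) -> np.ndarray:
    """Conformation for a point in mode space (inverse of :func:`project`).

    Weighted decompositions de-weight the output (divide by w per
    position) so the result lives in Angstrom space.
    """
    p = np.atleast_1d(np.asarray(p, dtype=float))
    l = decomp.modes.shape[1] if l is None else l
    if len(p) != l:
        raise ValueError(f"amplitude vector has length {len(p)}, expected {l}")
    x = decomp.modes[:, :l] @ p
    if decomp.scale is not None:
        x = x * decomp.scale
    x = x + decomp.center
    if decomp.weights is not None:
        x = x / _expand_weights(decomp.weights)
    return x


def motion_summary(decomp: MotionDecomposition) -> dict:
    """Standard per-ensemble report of the decomposition."""
    fractions = decomp.explained_fractions()
    return {
        "n": decomp.n,
        "m": decomp.m,
        "matrix_kind": decomp.matrix_kind,
        "dimensionality": {str(t): k for t, k in dimensionality_profile(decomp).items()},
        "top_mode_variance_fraction": float(fractions[0]) if len(fractions) else 0.0,
        "top_mode_collectivity": (collectivity(decomp.modes[:, 0], decomp.m)
                                  if decomp.modes.shape[1] else 0.0),
    }


def save_decomposition(decomp: MotionDecomposition, path: str | Path) -> None:
    """Serialize to a portable .npz archive (+ sidecar JSON summary)."""
    path = Path(path)
    np.savez(path,
             modes=decomp.modes, eigenvalues=decomp.eigenvalues,
             center=decomp.center,
             weights=np.array([]) if decomp.weights is None else decomp.weights,
             scale=np.array([]) if decomp.scale is None else decomp.scale,
             matrix_kind=np.array(decomp.matrix_kind),
             m=np.array(decomp.m), n=np.array(decomp.n))
    with open(path.with_suffix(".json"), "w") as handle:
        json.dump(motion_summary(decomp), handle, indent=1)


def load_decomposition(path: str | Path) -> MotionDecomposition:
    data = np.load(Path(path), allow_pickle=False)
    weights = data["weights"] if data["weights"].size else None
    scale = data["scale"] if data["scale"].size else None
    return MotionDecomposition(modes=data["modes"], eigenvalues=data["eigenvalues"],
                               center=data["center"],
                               matrix_kind=str(data["matrix_kind"]),
                               weights=weights, scale=scale,
                               m=int(data["m"]), n=int(data["n"]))
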