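"""Conformational ensembles: reference choice, superposition, redundancy.

An ensemble holds n conformations over the m columns of a cluster MSA as
an n x 3m Calpha coordinate matrix (NaN where a position is unresolved),
plus the full backbone per member for file output. The reference
conformation is the row whose sequence scores best against the MSA
consensus under BLOSUM62 (gap score -5). All conformations are then
centered and rotated onto the reference by the weighted least-squares
rotation; per-position weights reflecting MSA coverage can down-weight
poorly covered positions both here and in the downstream PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._substitution import AMINO_ACIDS, GAP, GAP_SCORE, blosum62, is_gap_like, self_score
from .grouping import Msa
from .structure_io import BackboneResidue, ChainRecord

CONSENSUS_ALPHABET = AMINO_ACIDS + GAP  # 21 symbols; 'X' counted as gap

DEFAULT_RMS_CUT = 0.1
DEFAULT_MIN_ALIGNED = 5


@dataclass
class ConsensusResult:
    consensus: str
    column_frequencies: np.ndarray  # m x 21, rows sum to 1


@dataclass
class RmsdMatrix:
    values: np.ndarray
    ids: list[str]


@dataclass
class ConformationalEnsemble:
    msa: Msa
    member_ids: list[str]
    R: np.ndarray                      # n x 3m, NaN where unresolved
    resolved_mask: np.ndarray          # n x m bool
    backbone_store: list[dict[int, BackboneResidue]]
    weights: Optional[np.ndarray] = None   # m-vector in (0, 1]
    reference_index: int = 0
    centering: str = "mean"
    superimposed: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.member_ids)

    @property
    def m(self) -> int:
        return self.resolved_mask.shape[1]

    def ca(self, i: int) -> np.ndarray:
        """Member i's Calpha coordinates as an m x 3 array (NaN rows allowed)."""
        return self.R[i].reshape(-1, 3)

    def subset(self, keep: list[int]) -> "ConformationalEnsemble":
        """Row-subset of the ensemble, preserving order of ``keep``."""
        ref_id = self.member_ids[self.reference_index]
        new_ids = [self.member_ids[i] for i in keep]
        return ConformationalEnsemble(
            msa=Msa([self.msa.rows[i] for i in keep]),
            member_ids=new_ids,
            R=self.R[keep].copy(),
            resolved_mask=self.resolved_mask[keep].copy(),
            backbone_store=[self.backbone_store[i] for i in keep],
            weights=None if self.weights is None else self.weights.copy(),
            reference_index=new_ids.index(ref_id) if ref_id in new_ids else 0,
            centering=self.centering,
            superimposed=self.superimposed,
            meta=dict(self.meta),
        )


def build_ensemble(records: dict[str, ChainRecord], msa: Msa) -> ConformationalEnsemble:
    """Assemble the coordinate matrix of an aligned cluster.

    Every non-gap character of an MSA row consumes the next residue of the
    corresponding chain record; uppercase characters contribute their
    Calpha (and backbone) coordinates. Columns without a single resolved
    residue are dropped so that every retained position carries at least
    one real coordinate.
    """
    n, m = msa.n_rows, msa.n_cols
    R = np.full((n, 3 * m), np.nan)
    mask = np.zeros((n, m), dtype=bool)
    store: list[dict[int, BackboneResidue]] = []
    for i, (rid, aligned) in enumerate(msa.rows):
        record = records[rid]
        row_store: dict[int, BackboneResidue] = {}
        cursor = 0
        for j, char in enumerate(aligned):
            if char == GAP:
                continue
            residue = record.residues[cursor]
            cursor += 1
            if residue.resolved and char.isupper():
                R[i, 3 * j:3 * j + 3] = residue.ca
                mask[i, j] = True
                row_store[j] = residue
        if cursor != len(record.residues):
            raise ValueError(f"MSA row {rid} does not match its chain record")
        store.append(row_store)

    keep_cols = np.flatnonzero(mask.any(axis=0))
    if len(keep_cols) < m:
        col_of = {int(c): k for k, c in enumerate(keep_cols)}
        msa = Msa([(rid, "".join(aligned[c] for c in keep_cols))
                   for rid, aligned in msa.rows])
        idx = np.concatenate([[3 * c, 3 * c + 1, 3 * c + 2] for c in keep_cols])
        R = R[:, idx]
        mask = mask[:, keep_cols]
        store = [{col_of[c]: br for c, br in row.items() if c in col_of}
                 for row in store]
    return ConformationalEnsemble(msa=msa, member_ids=msa.ids, R=R,
                                  resolved_mask=mask, backbone_store=store)


# ---------------------------------------------------------------------------
# consensus and reference
# ---------------------------------------------------------------------------

def consensus_sequence(msa: Msa, invert_priority: bool = False) -> ConsensusResult:
    """Per-column modal symbol over the 20 amino acids + gap.

    'X' counts as gap. Frequency ties are resolved by preferring an amino
    acid over a gap, then the higher BLOSUM62 self-score, then the
    alphabet; ``invert_priority`` flips the first two rules (robustness
    experiment: prefer gaps and lower-scored amino acids).
    """
    n, m = msa.n_rows, msa.n_cols
    freqs = np.zeros((m, 21))
    symbols = []
    for j in range(m):
        counts = np.zeros(21)
        for char in msa.column(j):
            sym = GAP if is_gap_like(char) else char.upper()
            counts[CONSENSUS_ALPHABET.index(sym)] += 1
        freqs[j] = counts / n
        best = counts.max()
        candidates = [CONSENSUS_ALPHABET[k] for k in np.flatnonzero(counts == best)]

        def rank(sym: str):
            gap_first = (sym == GAP) != invert_priority  # False sorts first
            score = self_score(sym) if sym != GAP else 0
            return (gap_first, score if invert_priority else -score, sym)

        symbols.append(min(candidates, key=rank))
    return ConsensusResult("".join(symbols), freqs)


def score_against_consensus(aligned_seq: str, consensus: str) -> int:
    """Similarity of an aligned row to the consensus sequence.

    Sum of BLOSUM62 scores over columns; any column where either symbol
    is a gap or 'X' contributes the gap score (-5). Lowercase (unresolved)
    residues are scored as their amino acid.
    """
    if len(aligned_seq) != len(consensus):
        raise ValueError("sequence and consensus lengths differ")
    return sum(blosum62(a, b) for a, b in zip(aligned_seq, consensus))


def select_reference(msa: Msa, invert_priority: bool = False) -> int:
    """Row index of the most consensus-like sequence (ties: smallest id)."""
    consensus = consensus_sequence(msa, invert_priority).consensus
    scores = [score_against_consensus(aligned, consensus) for _, aligned in msa.rows]
    best = max(scores)
    candidates = [i for i, s in enumerate(scores) if s == best]
    return min(candidates, key=lambda i: msa.rows[i][0])


def position_weights(msa: Msa) -> np.ndarray:
    """Per-column confidence: fraction of rows with a resolved residue."""
    n = msa.n_rows
    return np.array([sum(1 for c in msa.column(j) if c.isupper() and c != "X") / n
                     for j in range(msa.n_cols)])


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def optimal_rotation(P: np.ndarray, Q: np.ndarray,
                     w: Optional[np.ndarray] = None) -> np.ndarray:
    """Proper rotation minimizing sum_i w_i ||R p_i - q_i||^2.

    ``P`` and ``Q`` are N x 3 and already centered. SVD-based weighted
    Kabsch with reflection correction; an exact minimizer also in the
    degenerate (collinear) case.
    """
    if w is None:
        w = np.ones(len(P))
    H = (w[:, None] * P).T @ Q          # 3x3 cross-covariance
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    return Vt.T @ np.diag([1.0, 1.0, d]) @ U.T


def _weighted_centroid(points: np.ndarray, w: np.ndarray) -> np.ndarray:
    return (w[:, None] * points).sum(axis=0) / w.sum()


def _fit_points(ensemble: ConformationalEnsemble, i: int, cols: np.ndarray,
                atoms: str) -> tuple[np.ndarray, np.ndarray]:
    """(points, weights) used for fitting member i over columns ``cols``."""
    w = np.ones(ensemble.m) if ensemble.weights is None else ensemble.weights
    if atoms == "ca":
        return ensemble.ca(i)[cols], w[cols]
    pts, ws = [], []
    for c in cols:
        br = ensemble.backbone_store[i][int(c)]
        for p in (br.n, br.ca, br.c, br.o):
            if p is not None:
                pts.append(p)
                ws.append(w[c])
    return np.asarray(pts), np.asarray(ws)


def _apply_transform(ensemble: ConformationalEnsemble, i: int,
                     rotation: np.ndarray, pre: np.ndarray,
                     post: np.ndarray) -> None:
    ca = ensemble.ca(i)
    resolved = ensemble.resolved_mask[i]
    ca[resolved] = (ca[resolved] - pre) @ rotation.T + post
    ensemble.R[i] = ca.reshape(-1)
    ensemble.backbone_store[i] = {
        c: br.transformed(rotation, pre, post)
        for c, br in ensemble.backbone_store[i].items()}


def superimpose_ensemble(ensemble: ConformationalEnsemble, atoms: str = "ca",
                         min_aligned: int = DEFAULT_MIN_ALIGNED) -> ConformationalEnsemble:
    """Center and rotate every conformation onto the reference.

    Each conformation is fitted over the positions resolved in both it and
    the reference, minimizing the weighted squared deviation; its weighted
    centroid over those positions is moved onto the reference's.
    Conformations sharing fewer than ``min_aligned`` positions with the
    reference are dropped and listed in ``meta['dropped_min_aligned']``.
    """
    if atoms not in ("ca", "backbone"):
        raise ValueError(f"unknown atom selection: {atoms!r}")
    ref = ensemble.reference_index
    ref_mask = ensemble.resolved_mask[ref]

    # place the reference: weighted center of mass at the origin
    ref_cols = np.flatnonzero(ref_mask)
    ref_pts, ref_w = _fit_points(ensemble, ref, ref_cols, atoms)
    origin = _weighted_centroid(ref_pts, ref_w)
    _apply_transform(ensemble, ref, np.eye(3), origin, np.zeros(3))

    dropped: list[str] = []
    keep = []
    for i in range(ensemble.n):
        if i == ref:
            keep.append(i)
            continue
        shared = np.flatnonzero(ensemble.resolved_mask[i] & ref_mask)
        if len(shared) < min_aligned:
            dropped.append(ensemble.member_ids[i])
            continue
        P, w = _fit_points(ensemble, i, shared, atoms)
        Q, _ = _fit_points(ensemble, ref, shared, atoms)
        cP, cQ = _weighted_centroid(P, w), _weighted_centroid(Q, w)
        if np.linalg.matrix_rank(P - cP, tol=1e-8) < 2:
            warnings.warn(f"degenerate (collinear) fit for {ensemble.member_ids[i]}")
        rot = optimal_rotation(P - cP, Q - cQ, w)
        _apply_transform(ensemble, i, rot, cP, cQ)
        keep.append(i)

    result = ensemble.subset(keep) if dropped else ensemble
    result.superimposed = True
    result.weights = ensemble.weights
    result.meta["dropped_min_aligned"] = dropped
    return result


# ---------------------------------------------------------------------------
# redundancy and RMSD
# ---------------------------------------------------------------------------

def pair_rmsd(ensemble: ConformationalEnsemble, i: int, j: int) -> float:
    """Calpha RMSD over positions resolved in both members (common frame)."""
    shared = ensemble.resolved_mask[i] & ensemble.resolved_mask[j]
    if not shared.any():
        return np.nan
    d = ensemble.ca(i)[shared] - ensemble.ca(j)[shared]
    return float(np.sqrt((d ** 2).sum() / shared.sum()))


def _sequence_included(ensemble: ConformationalEnsemble, a: int, b: int) -> bool:
    """A's sequence is identical to or included in B's."""
    row_a = ensemble.msa.rows[a][1]
    row_b = ensemble.msa.rows[b][1]
    for ca, cb in zip(row_a, row_b):
        if ca != GAP and ca.upper() != cb.upper():
            return False
    extra = ensemble.resolved_mask[a] & ~ensemble.resolved_mask[b]
    return not extra.any()


def reduce_redundancy(ensemble: ConformationalEnsemble,
                      rms_cut: float = DEFAULT_RMS_CUT) -> ConformationalEnsemble:
    """Drop near-duplicate conformations.

    A conformation A is removed iff some retained B has RMSD(A, B) <
    ``rms_cut`` and A's sequence is identical to or included in B's.
    Candidates are visited with the reference first, then by descending
    resolved length and ascending id (keep-first), so the reference is
    never removed and the longest of two mutual near-duplicates survives.
    """
    ref = ensemble.reference_index
    order = sorted(range(ensemble.n),
                   key=lambda i: (i != ref, -int(ensemble.resolved_mask[i].sum()),
                                  ensemble.member_ids[i]))
    retained: list[int] = []
    removed: list[str] = []
    for i in order:
        dup = any(pair_rmsd(ensemble, i, j) < rms_cut
                  and _sequence_included(ensemble, i, j) for j in retained)
        if dup:
            removed.append(ensemble.member_ids[i])
        else:
            retained.append(i)
    retained.sort()
    result = ensemble.subset(retained) if removed else ensemble
    result.meta["removed_redundant"] = removed
    return result


def rmsd_matrix(ensemble: ConformationalEnsemble) -> RmsdMatrix:
    """All-to-all pairwise Calpha RMSDs in the common frame."""
    n = ensemble.n
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pair_rmsd(ensemble, i, j)
    if np.isnan(values).any():
        warnings.warn("some conformation pairs share no resolved position")
    return RmsdMatrix(values, list(ensemble.member_ids))


def fill_gaps(ensemble: ConformationalEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Dense coordinates with unresolved entries imputed; returns (R, center).

    Gaps are filled with the centering conformation: the per-column mean
    over resolved entries (default) or the reference conformation
    (positions unresolved in the reference fall back to the mean). The
    imputation leaves resolved entries untouched and shrinks the variance
    of poorly covered columns toward zero.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(ensemble.R, axis=0)
    if ensemble.centering == "reference":
        center = ensemble.R[ensemble.reference_index].copy()
        center[np.isnan(center)] = col_mean[np.isnan(center)]
    elif ensemble.centering == "mean":
        center = col_mean
    else:
        raise ValueError(f"unknown centering: {ensemble.centering!r}")
    dense = ensemble.R.copy()
    fill = np.broadcast_to(center, dense.shape)
    nan = np.isnan(dense)
    dense[nan] = fill[nan]
    return dense, center
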