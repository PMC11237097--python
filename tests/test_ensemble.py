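import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conformotion import SyntheticSpec, make_linear_motion_ensemble
from conformotion.ensemble import (consensus_sequence, fill_gaps, optimal_rotation,
                                   pair_rmsd, position_weights, reduce_redundancy,
                                   rmsd_matrix, score_against_consensus,
                                   select_reference, superimpose_ensemble)
from conformotion.grouping import Msa


class TestConsensus:
    @pytest.mark.parametrize("rows,expected", [
        ([("a", "A"), ("b", "A"), ("c", "-")], "A"),   # simple majority
        ([("a", "A"), ("b", "-")], "A"),               # amino acid over gap
        ([("a", "A"), ("b", "X")], "A"),               # 'X' counted as gap
        ([("a", "L"), ("b", "W")], "W"),               # BLOSUM62 self-score tie-break
        ([("a", "ACD"), ("b", "ACD")], "ACD"),
    ])
    def test_modal_symbol(self, rows, expected):
        assert consensus_sequence(Msa(rows)).consensus == expected

    def test_inverted_priority_rules(self):
        assert consensus_sequence(Msa([("a", "L"), ("b", "W")]),
                                  invert_priority=True).consensus == "L"
        assert consensus_sequence(Msa([("a", "A"), ("b", "-")]),
                                  invert_priority=True).consensus == "-"

    def test_column_frequencies_sum_to_one(self):
        res = consensus_sequence(Msa([("a", "AC-"), ("b", "AXW")]))
        assert np.allclose(res.column_frequencies.sum(axis=1), 1.0)


class TestConsensusScore:
    def test_match_scores_blosum_diagonal(self):
        assert score_against_consensus("AAAA", "AAAA") == 16  # 4 x sigma(A,A)

    def test_gap_positions_score_minus_five(self):
        assert score_against_consensus("A-", "AA") == 4 - 5
        assert score_against_consensus("--", "AA") == -10
        assert score_against_consensus("AX", "AA") == 4 - 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_against_consensus("AA", "AAA")


class TestReferenceSelection:
    def test_exact_consensus_row_selected(self):
        msa = Msa([("a", "ACDE"), ("b", "ACDE"), ("c", "WCDE")])
        assert select_reference(msa) == 0

    def test_tie_broken_by_smallest_id(self):
        msa = Msa([("a", "ACDE"), ("b", "ACDE")])
        assert select_reference(msa) == 0

    def test_gapped_row_never_beats_equal_ungapped_row(self):
        msa = Msa([("a", "ACDEFG"), ("b", "ACDEFG"), ("c", "AC--FG")])
        # brute-force oracle: score every row against the consensus
        consensus = consensus_sequence(msa).consensus
        scores = [score_against_consensus(r[1], consensus) for r in msa.rows]
        assert select_reference(msa) == int(np.argmax(scores))
        assert select_reference(msa) != 2


class TestPositionWeights:
    def test_direct_formula(self):
        msa = Msa([("a", "AC"), ("b", "AC"), ("c", "A-"), ("d", "Ac")])
        w = position_weights(msa)
        assert w[0] == 1.0
        assert w[1] == pytest.approx(0.5)  # lowercase = unresolved

    def test_in_unit_interval(self, linear_default):
        ens, truth, dense = linear_default
        w = position_weights(ens.msa)
        assert ((w > 0) & (w <= 1)).all()


def _transformed_copy(ens, i, rotation, translation):
    ens.R[i] = (ens.ca(i) @ rotation.T + translation).reshape(-1)


class TestSuperposition:
    def test_identity_when_equal_to_reference(self, linear_small):
        ens, truth, dense = linear_small
        ens2 = ens.subset(list(range(ens.n)))
        ens2 = superimpose_ensemble(ens2)
        ref = ens2.reference_index
        # a conformation equal to the reference stays at RMSD 0
        ens2.R[0] = ens2.R[ref].copy()
        ens3 = superimpose_ensemble(ens2)
        assert pair_rmsd(ens3, 0, ref) < 1e-10

    def test_known_rotation_recovered(self, linear_small):
        ens, truth, dense = linear_small
        ens2 = ens.subset(list(range(ens.n)))
        ens2 = superimpose_ensemble(ens2)
        ref = ens2.reference_index
        before = pair_rmsd(ens2, 1, ref)
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        _transformed_copy(ens2, 1, rot, np.array([5.0, -2.0, 9.0]))
        ens3 = superimpose_ensemble(ens2)
        assert pair_rmsd(ens3, 1, ref) == pytest.approx(before, abs=1e-8)

    def test_idempotent(self, linear_default):
        ens, truth, dense = linear_default
        once = ens.R.copy()
        again = superimpose_ensemble(ens)
        assert np.allclose(np.nan_to_num(once), np.nan_to_num(again.R), atol=1e-8)

    def test_weight_zero_outlier_matches_subset_fit(self, rng):
        """Zero-weight positions must not influence the fit (oracle: scipy)."""
        P = rng.normal(size=(10, 3))
        true_rot = Rotation.random(random_state=7)
        Q = true_rot.apply(P)
        P_out = P.copy()
        P_out[0] += [8.0, -3.0, 5.0]       # corrupted position
        w = np.ones(10)
        w[0] = 0.0
        Pc = P_out - (w[:, None] * P_out).sum(0) / w.sum()
        Qc = Q - (w[:, None] * Q).sum(0) / w.sum()
        rot = optimal_rotation(Pc, Qc, w)
        oracle, _ = Rotation.align_vectors(Qc[1:], Pc[1:])
        assert np.allclose(rot, oracle.as_matrix(), atol=1e-8)

    def test_uniform_weights_match_classical_kabsch(self, rng):
        P = rng.normal(size=(15, 3))
        Q = Rotation.random(random_state=3).apply(P) + rng.normal(scale=0.1,
                                                                  size=(15, 3))
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        weighted = optimal_rotation(Pc, Qc, np.ones(15))
        oracle, _ = Rotation.align_vectors(Qc, Pc)
        assert np.allclose(weighted, oracle.as_matrix(), atol=1e-8)

    def test_objective_beats_random_rotations(self, rng):
        """Monte-Carlo optimality of the weighted least-squares objective."""
        P = rng.normal(size=(8, 3))
        Q = rng.normal(size=(8, 3))
        w = rng.uniform(0.1, 1.0, 8)
        Pc = P - (w[:, None] * P).sum(0) / w.sum()
        Qc = Q - (w[:, None] * Q).sum(0) / w.sum()
        rot = optimal_rotation(Pc, Qc, w)

        def objective(R):
            return (w[:, None] * (Pc @ R.T - Qc) ** 2).sum() / w.sum()

        best = objective(rot)
        random_rots = Rotation.random(1000, random_state=11).as_matrix()
        assert all(best <= objective(R) + 1e-12 for R in random_rots)

    def test_min_aligned_drops_sparse_conformations(self, linear_small):
        ens, truth, dense = linear_small
        ens2 = ens.subset(list(range(ens.n)))
        victim = 3 if ens2.reference_index != 3 else 4
        # leave only 4 resolved positions on the victim
        ens2.resolved_mask[victim, 4:] = False
        ens2.R[victim, 12:] = np.nan
        result = superimpose_ensemble(ens2, min_aligned=5)
        assert result.n == ens.n - 1
        assert len(result.meta["dropped_min_aligned"]) == 1


class TestRedundancy:
    @pytest.fixture()
    def ens(self, linear_small):
        base, truth, dense = linear_small
        e = base.subset(list(range(base.n)))
        return superimpose_ensemble(e)

    def test_exact_duplicate_removed(self, ens):
        dup = ens.subset(list(range(ens.n)) + [ens.n - 1])
        # subset with a repeated index duplicates the last member under a new id
        dup.member_ids[-1] = "ZZZZ_A"
        dup.msa.rows[-1] = ("ZZZZ_A", dup.msa.rows[-2][1])
        result = reduce_redundancy(dup, rms_cut=0.1)
        assert result.n == ens.n
        # exactly one of the two mutual duplicates is removed (order-defined)
        assert len(result.meta["removed_redundant"]) == 1
        assert result.meta["removed_redundant"][0] in {"ZZZZ_A",
                                                       dup.member_ids[-2]}

    def test_close_but_disjoint_sequences_kept(self, ens):
        close = ens.subset([0, 1])
        close.R[1] = close.R[0] + 0.01    # RMSD ~0.017 A
        # disjoint resolved sets at one position
        close.resolved_mask[0, 0] = False
        close.R[0, 0:3] = np.nan
        rows = close.msa.rows
        rows[0] = (rows[0][0], "-" + rows[0][1][1:])
        seq1 = rows[1][1]
        rows[1] = (rows[1][0], seq1[:-1] + "-")
        close.resolved_mask[1, -1] = False
        close.R[1, -3:] = np.nan
        result = reduce_redundancy(close, rms_cut=0.1)
        assert result.n == 2

    def test_truncation_removed_as_included_sequence(self, ens):
        trunc = ens.subset([0, 1])
        keep_from = trunc.reference_index
        other = 1 - keep_from
        trunc.R[other] = trunc.R[keep_from].copy()
        trunc.resolved_mask[other] = trunc.resolved_mask[keep_from].copy()
        # truncate the copy: drop its last 5 positions
        trunc.resolved_mask[other, -5:] = False
        trunc.R[other, -15:] = np.nan
        rid, row = trunc.msa.rows[other]
        trunc.msa.rows[other] = (rid, row[:-5] + "-----")
        result = reduce_redundancy(trunc, rms_cut=0.1)
        assert result.n == 1
        assert result.member_ids[0] == trunc.member_ids[keep_from]

    def test_never_removes_reference_never_grows(self, ens):
        result = reduce_redundancy(ens)
        ref_id = ens.member_ids[ens.reference_index]
        assert ref_id in result.member_ids
        assert result.n <= ens.n


class TestRmsdMatrix:
    def test_single_member(self, linear_small):
        ens, truth, dense = linear_small
        single = ens.subset([0])
        assert rmsd_matrix(single).values.shape == (1, 1)
        assert rmsd_matrix(single).values[0, 0] == 0.0

    def test_matches_bruteforce_double_loop(self, linear_default):
        ens, truth, dense = linear_default
        mat = rmsd_matrix(ens).values
        for i in range(0, ens.n, 7):
            for j in range(0, ens.n, 5):
                shared = ens.resolved_mask[i] & ens.resolved_mask[j]
                diff = ens.ca(i)[shared] - ens.ca(j)[shared]
                expected = np.sqrt((diff ** 2).sum() / shared.sum())
                assert mat[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_zero_diagonal(self, linear_default):
        ens, truth, dense = linear_default
        mat = rmsd_matrix(ens).values
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)


class TestFillGaps:
    def test_fully_resolved_unchanged(self, linear_small):
        ens, truth, dense = linear_small
        filled, center = fill_gaps(ens)
        assert np.array_equal(filled, ens.R)

    def test_single_resolved_column_has_zero_variance(self):
        """Symbolic oracle: one real value + (n-1) copies of the resolved
        mean (= that value) has variance exactly 0."""
        ens, truth = make_linear_motion_ensemble(
            SyntheticSpec(m=12, n=6, noise_sd=0.1, seed=9))
        col = 5
        keep_row = 2
        for i in range(ens.n):
            if i != keep_row:
                ens.resolved_mask[i, col] = False
                ens.R[i, 3 * col:3 * col + 3] = np.nan
        filled, center = fill_gaps(ens)
        var = filled[:, 3 * col:3 * col + 3].var(axis=0, ddof=1)
        assert np.allclose(var, 0.0)

    def test_reference_centering_uses_reference_row(self, linear_default):
        ens, truth, dense = linear_default
        ens2 = ens.subset(list(range(ens.n)))
        ens2.centering = "reference"
        filled, center = fill_gaps(ens2)
        ref = ens2.reference_index
        resolved = ~np.isnan(ens2.R[ref])
        assert np.array_equal(center[resolved], ens2.R[ref][resolved])
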