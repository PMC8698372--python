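import numpy as np
import pytest

import oracle
from sdpscan import (
    Alignment,
    ScoreRecord,
    ScoringError,
    SimilarityMatrix,
    global_similarity_matrix,
    position_similarity_matrix,
    rank_scores,
    score_all,
    spearman_matrix_correlation,
)
from conftest import random_alignment


class TestSimilarityMatrix:
    def test_pair_lookup_matches_square(self):
        square = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        sm = SimilarityMatrix.from_square(("a", "b", "c"), square)
        assert sm.value("a", "b") == 1
        assert sm.value("c", "a") == 2
        assert sm.value("b", "c") == 3

    def test_diagonal_not_stored(self):
        sm = SimilarityMatrix.from_square(("a", "b", "c"), np.eye(3))
        assert len(sm.condensed) == 3
        with pytest.raises(ScoringError):
            sm.value("a", "a")

    def test_size_mismatch_rejected(self):
        with pytest.raises(ScoringError):
            SimilarityMatrix(labels=("a", "b", "c"), condensed=np.zeros(2))


class TestGlobalSimilarityMatrix:
    def test_identical_sequences_attain_pair_maximum(self, mclachlan):
        aln = Alignment(ids=("a", "b", "c"), rows=("AWDY", "AWDY", "AWDY"))
        got = global_similarity_matrix(aln, mclachlan)
        expected = np.mean([mclachlan.value(ch, ch) for ch in "AWDY"])
        assert got.value("a", "b") == pytest.approx(expected)

    def test_disjoint_gap_patterns_give_zero(self, mclachlan):
        aln = Alignment(ids=("a", "b", "c"), rows=("AC--", "--DE", "ACDE"))
        got = global_similarity_matrix(aln, mclachlan)
        assert got.value("a", "b") == 0.0

    def test_gap_column_contributes_zero_with_full_denominator(self, mclachlan):
        aln = Alignment(ids=("a", "b", "c"), rows=("AW-Y", "AWDY", "AWDY"))
        got = global_similarity_matrix(aln, mclachlan)
        expected = sum(mclachlan.value(ch, ch) for ch in "AWY") / 4.0
        assert got.value("a", "b") == pytest.approx(expected)

    def test_toy_alignment_matches_brute_force(self, toy_alignment, mclachlan):
        got = global_similarity_matrix(toy_alignment, mclachlan)
        expected = oracle.global_pair_vector(toy_alignment, mclachlan)
        assert np.allclose(got.condensed, expected, atol=1e-12)


class TestPositionSimilarityMatrix:
    def test_gap_zeroes_every_pair_of_that_protein(self, mclachlan, scales):
        aln = Alignment(ids=("a", "b", "c", "d"), rows=("A", "-", "V", "L"))
        for channel in (mclachlan, scales[0]):
            sm = position_similarity_matrix(aln, aln.column(1), channel)
            assert sm.value("a", "b") == 0.0
            assert sm.value("b", "c") == 0.0
            assert sm.value("b", "d") == 0.0
            assert sm.value("a", "c") != 0.0

    def test_conserved_column_is_constant_maxdiff(self, scales):
        aln = Alignment(ids=("a", "b", "c"), rows=("W", "W", "W"))
        s = scales[0]
        sm = position_similarity_matrix(aln, aln.column(1), s)
        assert np.allclose(sm.condensed, s.maxdiff, atol=1e-9)

    def test_two_block_column_structure(self, scales):
        kd = next(s for s in scales if s.name == "hdf_KD")
        aln = Alignment(ids=("a", "b", "c", "d"), rows=("A", "A", "V", "V"))
        sm = position_similarity_matrix(aln, aln.column(1), kd)
        within = kd.maxdiff
        cross = kd.maxdiff - abs(kd.value("A") - kd.value("V"))
        assert sm.value("a", "b") == pytest.approx(within, abs=1e-9)
        assert sm.value("c", "d") == pytest.approx(within, abs=1e-9)
        for pair in [("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]:
            assert sm.value(*pair) == pytest.approx(cross, abs=1e-9)


class TestSpearmanMatrixCorrelation:
    def _sm(self, vec):
        # labels sized to fit a condensed vector of 6 entries (4 proteins)
        return SimilarityMatrix(labels=("a", "b", "c", "d"), condensed=np.array(vec))

    def test_self_correlation_is_one(self):
        a = self._sm([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert spearman_matrix_correlation(a, a) == pytest.approx(1.0)

    def test_order_reversal_gives_minus_one(self):
        a = self._sm([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = self._sm([10.0, 8.0, 7.0, 5.0, 2.0, 1.0])
        assert spearman_matrix_correlation(a, b) == pytest.approx(-1.0)

    def test_tied_entries_match_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 6.0, 5.0]
        got = spearman_matrix_correlation(self._sm(x), self._sm(y))
        assert got == pytest.approx(oracle.rho(x, y), abs=1e-12)

    def test_constant_vector_is_undefined(self):
        a = self._sm([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        c = self._sm([2.0] * 6)
        assert spearman_matrix_correlation(a, c) is None
        assert spearman_matrix_correlation(c, a) is None

    def test_label_mismatch_rejected(self):
        a = self._sm([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        b = SimilarityMatrix(labels=("a", "b", "d", "c"),
                             condensed=np.arange(6.0))
        with pytest.raises(ScoringError, match="different protein"):
            spearman_matrix_correlation(a, b)


class TestScoreAll:
    def test_gap_threshold_boundary(self, channels, mclachlan):
        # 10 proteins: column 1 has exactly 10% gaps (scored), column 2 has
        # 20% (excluded), column 3 is gap-free.
        n = 10
        rows = []
        residues = "ACDEFGHIKL"
        for i in range(n):
            c1 = "-" if i == 0 else residues[i]
            c2 = "-" if i < 2 else residues[i]
            rows.append(c1 + c2 + residues[i] + "WYWYW"[i % 5])
        aln = Alignment(ids=tuple(f"p{i}" for i in range(n)), rows=tuple(rows))
        target = global_similarity_matrix(aln, mclachlan)
        records = score_all(aln, channels, target, gap_threshold=0.10)
        cols = {r.column for r in records}
        assert 1 in cols and 3 in cols
        assert 2 not in cols

    def test_fully_conserved_column_is_undefined_for_every_channel(
            self, channels, mclachlan):
        aln = Alignment(ids=("a", "b", "c", "d"), rows=("WA", "WC", "WD", "WE"))
        target = global_similarity_matrix(aln, mclachlan)
        records = score_all(aln, channels, target)
        col1 = [r for r in records if r.column == 1]
        assert len(col1) == len(channels)
        assert all(r.score is None for r in col1)

    def test_nothing_to_score_raises(self, channels, mclachlan):
        aln = Alignment(ids=("a", "b", "c"), rows=("A-", "-C", "A-"))
        target = global_similarity_matrix(aln, mclachlan)
        with pytest.raises(ScoringError, match="nothing to score"):
            score_all(aln, channels, target, gap_threshold=0.10)

    def test_target_label_mismatch_rejected(self, channels, toy_alignment):
        bad = SimilarityMatrix(labels=("x", "y", "z"), condensed=np.arange(3.0))
        with pytest.raises(ScoringError, match="target"):
            score_all(toy_alignment, channels, bad)


class TestRankScores:
    def _rec(self, column, prop, score):
        return ScoreRecord(column=column, reference_residue="A",
                           reference_number=column, property=prop, score=score)

    def test_descending_with_stated_tie_breaks(self):
        records = [
            self._rec(5, "pol_G", 0.9),
            self._rec(2, "hdf_KD", 0.9),
            self._rec(2, "", 0.9),
            self._rec(1, "MW", 0.95),
            self._rec(3, "flex", None),
            self._rec(9, "coil", 0.1),
        ]
        table = rank_scores(records)
        key = [(r.column, r.property) for r in table]
        # equal scores: lower column first, then property label, empty first
        assert key == [(1, "MW"), (2, ""), (2, "hdf_KD"), (5, "pol_G"), (9, "coil")]

    def test_undefined_scores_excluded(self):
        table = rank_scores([self._rec(1, "MW", None)])
        assert len(table) == 0

    def test_top_zero_is_empty(self):
        table = rank_scores([self._rec(1, "MW", 0.5)], top=0)
        assert len(table) == 0

    def test_tsv_output_shape(self):
        import io
        table = rank_scores([self._rec(1, "MW", 0.56789), self._rec(2, "", 0.1)])
        buf = io.StringIO()
        table.to_tsv(buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "Position\tRefResidue\tRefNumber\tProperty\tScore"
        assert lines[1] == "1\tA\t1\tMW\t0.5679"
        assert lines[2].split("\t")[3] == ""


class TestInvariances:
    def _scores(self, aln, channels, mclachlan):
        target = global_similarity_matrix(aln, mclachlan)
        return {(r.column, r.property): r.score
                for r in score_all(aln, channels, target, gap_threshold=0.5)}

    def test_protein_permutation_leaves_scores_unchanged(self, channels, mclachlan):
        rng = np.random.default_rng(11)
        aln = random_alignment(rng, n_min=5, n_max=5, len_max=8)
        perm = rng.permutation(aln.n_sequences)
        shuffled = Alignment(ids=tuple(aln.ids[i] for i in perm),
                             rows=tuple(aln.rows[i] for i in perm))
        a = self._scores(aln, channels, mclachlan)
        b = self._scores(shuffled, channels, mclachlan)
        assert a.keys() == b.keys()
        for k in a:
            if a[k] is None:
                assert b[k] is None
            else:
                assert a[k] == pytest.approx(b[k], abs=1e-12)

    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (3.0, 10.0), (0.25, -7.5)])
    def test_affine_scale_transform_leaves_scores_unchanged(
            self, scales, mclachlan, a, b):
        kd = next(s for s in scales if s.name == "hdf_KD")
        rng = np.random.default_rng(13)
        aln = random_alignment(rng, n_min=6, n_max=6, len_max=10)
        target = global_similarity_matrix(aln, mclachlan)
        base = score_all(aln, [kd], target, gap_threshold=0.5)
        moved = score_all(aln, [kd.transformed(a, b)], target, gap_threshold=0.5)
        for r1, r2 in zip(base, moved):
            if r1.score is None:
                assert r2.score is None
            else:
                assert r1.score == pytest.approx(r2.score, abs=1e-12)


class TestOracleAgreement:
    def test_small_random_alignments_match_brute_force(self, channels, mclachlan):
        rng = np.random.default_rng(29)
        for _ in range(25):
            aln = random_alignment(rng)
            target = global_similarity_matrix(aln, mclachlan)
            try:
                records = score_all(aln, channels, target, gap_threshold=0.4)
            except ScoringError:
                assert not oracle.score_alignment(aln, channels, mclachlan,
                                                  gap_threshold=0.4)
                continue
            expected = oracle.score_alignment(aln, channels, mclachlan,
                                              gap_threshold=0.4)
            got = {(r.column, r.property): r.score for r in records}
            assert got.keys() == expected.keys()
            for k, want in expected.items():
                if want is None:
                    assert got[k] is None
                else:
                    assert got[k] == pytest.approx(want, abs=1e-10)
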