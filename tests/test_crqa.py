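"""Cross-recurrence plots and CRQA metrics against brute-force oracles."""

import numpy as np
import pytest

from cardiosync.crqa import (
    RecurrencePlot,
    cross_recurrence,
    crqa_metrics,
    determinism,
    diagonal_line_histogram,
    select_threshold_global,
    select_threshold_pair,
    vertical_line_histogram,
)
from cardiosync.embedding import delay_embed
from oracles import brute_crqa_metrics, brute_diagonal_lengths, \
    brute_vertical_lengths


def _plot(mat):
    return RecurrencePlot(matrix=np.asarray(mat, dtype=bool),
                          epsilon=0.2, norm="rms")


class TestCrossRecurrence:
    def test_self_pair_has_full_diagonal(self, rng):
        emb = delay_embed(rng.standard_normal(40), m=2)
        plot = cross_recurrence(emb, emb, epsilon=1e-9, norm="euclidean")
        assert np.all(np.diag(plot.matrix))

    def test_large_offset_empty_plot(self, rng):
        x = rng.standard_normal(40)
        a = delay_embed(x, m=2)
        b = delay_embed(x + 100.0, m=2)
        plot = cross_recurrence(a, b, epsilon=0.5, norm="euclidean")
        assert not plot.matrix.any()

    def test_five_point_identity(self):
        a = delay_embed(np.arange(5.0), m=1)
        plot = cross_recurrence(a, a, epsilon=0.5, norm="euclidean")
        np.testing.assert_array_equal(plot.matrix, np.eye(5, dtype=bool))
        assert crqa_metrics(plot).rec == pytest.approx(5 / 25)

    def test_mismatched_embeddings_rejected(self, rng):
        a = delay_embed(rng.standard_normal(30), m=2)
        b = delay_embed(rng.standard_normal(30), m=3)
        with pytest.raises(ValueError, match="mismatched"):
            cross_recurrence(a, b, epsilon=0.2)

    def test_transpose_symmetry(self, rng):
        a = delay_embed(rng.standard_normal(60), m=3)
        b = delay_embed(rng.standard_normal(60), m=3)
        ab = cross_recurrence(a, b, epsilon=1.0, norm="rms")
        ba = cross_recurrence(b, a, epsilon=1.0, norm="rms")
        np.testing.assert_array_equal(ab.matrix.T, ba.matrix)
        m_ab, m_ba = crqa_metrics(ab), crqa_metrics(ba)
        assert m_ab.rec == pytest.approx(m_ba.rec, abs=1e-15)
        assert m_ab.ent == pytest.approx(m_ba.ent, abs=1e-15)
        assert m_ab.lmax == m_ba.lmax
        # lam of one orientation equals the horizontal-line analogue of
        # the other, i.e. lam computed on the transposed matrix
        assert m_ab.lam == pytest.approx(
            crqa_metrics(_plot(ba.matrix.T)).lam, abs=1e-15
        )


class TestLineHistograms:
    def test_identity_matrix_single_diagonal(self):
        assert diagonal_line_histogram(_plot(np.eye(5)), l_min=2) == {5: 1}

    def test_empty_matrix(self):
        assert diagonal_line_histogram(_plot(np.zeros((4, 4)))) == {}
        assert vertical_line_histogram(_plot(np.zeros((4, 4)))) == {}

    def test_hand_built_diagonal_runs(self):
        mat = np.zeros((8, 8), dtype=bool)
        for k in range(3):           # run of 3 on the main diagonal
            mat[k, k] = True
        for k in range(3):           # run of 3 on offset +3
            mat[k + 1, k + 4] = True
        mat[6, 1] = mat[7, 2] = True  # run of 2 below the diagonal
        assert diagonal_line_histogram(_plot(mat), l_min=2) == {3: 2, 2: 1}

    def test_identity_has_no_vertical_lines(self):
        assert vertical_line_histogram(_plot(np.eye(6)), v_min=2) == {}

    def test_full_column(self):
        mat = np.zeros((6, 4), dtype=bool)
        mat[:, 2] = True
        assert vertical_line_histogram(_plot(mat), v_min=2) == {6: 1}

    def test_random_matrix_matches_column_scan(self, rng):
        mat = rng.random((20, 20)) < 0.3
        hist = vertical_line_histogram(_plot(mat), v_min=2)
        brute = {}
        for l in brute_vertical_lengths(mat):
            if l >= 2:
                brute[l] = brute.get(l, 0) + 1
        assert hist == brute

    def test_random_matrix_matches_diagonal_scan(self, rng):
        mat = rng.random((17, 23)) < 0.3
        hist = diagonal_line_histogram(_plot(mat), l_min=2)
        brute = {}
        for l in brute_diagonal_lengths(mat):
            if l >= 2:
                brute[l] = brute.get(l, 0) + 1
        assert hist == brute


class TestMetrics:
    def test_identity_plot_metrics(self):
        m = crqa_metrics(_plot(np.eye(5)))
        assert m.rec == pytest.approx(0.2)
        assert m.lmax == 5
        assert m.ent == 0.0
        assert m.lam == 0.0

    def test_empty_plot_all_zero(self):
        m = crqa_metrics(_plot(np.zeros((7, 9))))
        assert (m.rec, m.ent, m.lam, m.lmax) == (0.0, 0.0, 0.0, 0)

    @pytest.mark.parametrize("normalized", [False, True])
    def test_seeded_noise_plots_match_oracle(self, rng, normalized):
        for _ in range(10):
            a = delay_embed(rng.standard_normal(60), m=3)
            b = delay_embed(rng.standard_normal(60), m=3)
            plot = cross_recurrence(a, b, epsilon=1.2, norm="rms")
            got = crqa_metrics(plot, entropy_normalized=normalized)
            rec, ent, lam, lmax = brute_crqa_metrics(
                plot.matrix, entropy_normalized=normalized
            )
            assert got.rec == pytest.approx(rec, abs=1e-12)
            assert got.ent == pytest.approx(ent, abs=1e-12)
            assert got.lam == pytest.approx(lam, abs=1e-12)
            assert got.lmax == lmax

    def test_entropy_zero_for_single_length(self):
        mat = np.zeros((10, 10), dtype=bool)
        mat[0, 0] = mat[1, 1] = True   # one line of length 2
        mat[5, 0] = mat[6, 1] = True   # another line of length 2
        assert crqa_metrics(_plot(mat)).ent == 0.0

    def test_determinism_of_identity_plot(self):
        assert determinism(_plot(np.eye(4))) == pytest.approx(1.0)

    def test_rec_monotone_in_epsilon(self, rng):
        a = delay_embed(rng.standard_normal(80), m=2)
        b = delay_embed(rng.standard_normal(80), m=2)
        recs = [
            crqa_metrics(cross_recurrence(a, b, epsilon=e, norm="rms")).rec
            for e in np.linspace(0.1, 2.5, 10)
        ]
        assert np.all(np.diff(recs) >= 0)


class TestThresholdSelection:
    def test_single_candidate_returned(self, rng):
        a = delay_embed(rng.standard_normal(40), m=2)
        b = delay_embed(rng.standard_normal(40), m=2)
        assert select_threshold_pair(a, b, [0.7]) == 0.7

    def test_constant_series_tie_gives_smallest(self):
        a = delay_embed(np.zeros(30), m=2)
        grid = [0.1, 0.2, 0.3]
        assert select_threshold_pair(a, a, grid) == 0.1

    def test_matches_exhaustive_grid_search(self, rng):
        a = delay_embed(rng.standard_normal(50), m=2)
        b = delay_embed(rng.standard_normal(50), m=2)
        grid = np.arange(0.05, 0.55, 0.05)
        chosen = select_threshold_pair(a, b, grid, norm="rms")
        # independent exhaustive evaluation
        from cardiosync.crqa import distance_matrix
        best, best_score = None, -1.0
        for eps in np.sort(grid):
            lengths = brute_diagonal_lengths(
                distance_matrix(a, b, "rms") <= eps
            )
            kept = np.array([l for l in lengths if l >= 2])
            score = kept.std() if kept.size else 0.0
            if score > best_score + 1e-15:
                best, best_score = eps, score
        assert chosen == pytest.approx(best)

    def test_all_empty_returns_smallest_with_warning(self, rng, caplog):
        a = delay_embed(rng.standard_normal(30), m=2)
        b = delay_embed(rng.standard_normal(30) + 50, m=2)
        with caplog.at_level("WARNING"):
            assert select_threshold_pair(a, b, [0.1, 0.2]) == 0.1

    def test_global_threshold_is_mean(self):
        assert select_threshold_global([0.1, 0.3]) == pytest.approx(0.2)
        assert select_threshold_global([0.2]) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            select_threshold_global([])
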