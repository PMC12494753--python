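"""Profiles, AUC/ROC/STD scores, AHP aggregation, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import tsgate as tg
from tsgate.analysis import AXIS_CELL, AXIS_CHANNEL, AXIS_TIME_STEP

from conftest import brute_force_grad_scores

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


def archive_from_epoch_batches(values, mode=tg.MODE_CHANNEL):
    """Build an archive from a nested (epochs, batches, features...) list."""
    return tg.GradientArchive(entries=np.asarray(values, dtype=float), mode=mode)


class TestWeightNaive:
    def test_absolute_magnitude_and_ranking(self):
        ext = tg.make_extension(4, 3, tg.MODE_CHANNEL)
        ext.weights = np.array([1.5, -2.0, 0.1])
        est = tg.weight_naive_scores(ext)
        np.testing.assert_array_equal(est.scores, [1.5, 2.0, 0.1])
        np.testing.assert_array_equal(est.ranking, [1, 0, 2])

    def test_untrained_gate_warns_and_ties_break_by_index(self):
        ext = tg.make_extension(4, 5, tg.MODE_CHANNEL)
        with pytest.warns(UserWarning, match="degenerate"):
            est = tg.weight_naive_scores(ext)
        np.testing.assert_array_equal(est.scores, np.ones(5))
        np.testing.assert_array_equal(est.ranking, np.arange(5))

    def test_matrix_mode_cell_scores(self):
        ext = tg.make_extension(2, 2, tg.MODE_MATRIX)
        ext.weights = np.array([[1.0, -3.0], [0.0, 2.0]])
        est = tg.weight_naive_scores(ext)
        np.testing.assert_array_equal(est.as_matrix(), [[1.0, 3.0], [0.0, 2.0]])
        assert est.feature_axis == AXIS_CELL


class TestBuildProfile:
    def test_sum_profile_hand_example(self):
        arc = archive_from_epoch_batches([[[1.0], [2.0]], [[3.0], [-1.0]]])
        prof = tg.build_profile(arc, gamma="sum", feature_axis=AXIS_CHANNEL)
        np.testing.assert_allclose(prof.values[:, 0], [3.0, 2.0])

    def test_std_profile_hand_example(self):
        arc = archive_from_epoch_batches([[[1.0], [2.0]], [[3.0], [-1.0]]])
        prof = tg.build_profile(arc, gamma="std", feature_axis=AXIS_CHANNEL)
        # sample sd (ddof 1) of (1,2) and (3,-1)
        np.testing.assert_allclose(
            prof.values[:, 0], [0.7071067811865476, 2.8284271247461903]
        )

    def test_zero_archive_zero_profile(self):
        arc = archive_from_epoch_batches(np.zeros((3, 4, 2)))
        for gamma in ("sum", "std"):
            prof = tg.build_profile(arc, gamma=gamma)
            assert np.all(prof.values == 0.0)

    def test_single_batch_std_warns_zero(self):
        arc = archive_from_epoch_batches(np.ones((3, 1, 2)))
        with pytest.warns(UserWarning, match="single batch"):
            prof = tg.build_profile(arc, gamma="std")
        assert np.all(prof.values == 0.0)

    def test_matrix_archive_channel_reduction_is_time_sum(self, rng):
        entries = rng.normal(size=(3, 2, 5, 4))
        arc = tg.GradientArchive(entries=entries, mode=tg.MODE_MATRIX)
        prof = tg.build_profile(arc, gamma="sum", feature_axis=AXIS_CHANNEL)
        np.testing.assert_allclose(prof.values, entries.sum(axis=2).sum(axis=1))


class TestAuc:
    def test_constant_sequence_closed_form(self):
        for e in (1, 2, 5, 9):
            v = np.full(e, 3.5)
            expected = 3.5 if e == 1 else 3.5 * (e - 1)
            assert tg.auc(v) == pytest.approx(expected)

    def test_zeros(self):
        assert tg.auc(np.zeros(7)) == 0.0

    def test_hand_trapezoid(self):
        assert tg.auc([0.0, 2.0, 0.0]) == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(tg.DimensionError):
            tg.auc([])


class TestRoc:
    def test_constant(self):
        np.testing.assert_allclose(tg.roc([4.0] * 5), [4.0, 0, 0, 0, 0])

    def test_hand_differencing(self):
        np.testing.assert_allclose(tg.roc([1.0, 3.0, 2.0]), [1.0, 2.0, -1.0])

    def test_zeros(self):
        np.testing.assert_allclose(tg.roc(np.zeros(4)), np.zeros(4))

    def test_too_short(self):
        with pytest.raises(tg.DimensionError):
            tg.roc([1.0])


class TestGradScores:
    def test_constant_profile_closed_form(self):
        # feature A: per-epoch sum 2 for 3 epochs -> |auc| = 2*(3-1) = 4
        entries = np.zeros((3, 1, 2))
        entries[:, 0, 0] = 2.0
        arc = archive_from_epoch_batches(entries)
        est = tg.grad_scores(arc, "grad_auc")
        np.testing.assert_allclose(est.scores, [4.0, 0.0])
        np.testing.assert_array_equal(est.ranking, [0, 1])

    @pytest.mark.parametrize("method", tg.GRAD_METHODS)
    @pytest.mark.parametrize(
        "mode,axis",
        [
            (tg.MODE_CHANNEL, AXIS_CHANNEL),
            (tg.MODE_MATRIX, AXIS_CHANNEL),
            (tg.MODE_MATRIX, AXIS_TIME_STEP),
            (tg.MODE_MATRIX, AXIS_CELL),
        ],
    )
    def test_oracle_equivalence(self, method, mode, axis, rng):
        shape = (6, 4, 5) if mode == tg.MODE_CHANNEL else (6, 4, 3, 5)
        entries = rng.normal(size=shape)
        arc = tg.GradientArchive(entries=entries, mode=mode)
        est = tg.grad_scores(arc, method, feature_axis=axis)
        oracle = brute_force_grad_scores(entries, mode, method, axis)
        np.testing.assert_allclose(est.scores, oracle, rtol=1e-12)

    def test_identical_features_tie_break_by_index(self, rng):
        col = rng.normal(size=(5, 3, 1))
        entries = np.repeat(col, 4, axis=2)
        arc = tg.GradientArchive(entries=entries, mode=tg.MODE_CHANNEL)
        for method in tg.GRAD_METHODS:
            est = tg.grad_scores(arc, method)
            assert np.allclose(est.scores, est.scores[0])
            np.testing.assert_array_equal(est.ranking, np.arange(4))

    def test_grad_std_nonnegative(self, rng):
        arc = tg.GradientArchive(
            entries=rng.normal(size=(4, 6, 7)), mode=tg.MODE_CHANNEL
        )
        est = tg.grad_scores(arc, "grad_std")
        assert np.all(est.scores >= 0.0)

    def test_axis_incompatible_with_mode(self, rng):
        arc = tg.GradientArchive(entries=rng.normal(size=(3, 2, 4)), mode=tg.MODE_CHANNEL)
        with pytest.raises(tg.DimensionError):
            tg.grad_scores(arc, "grad_auc", feature_axis=AXIS_CELL)

    def test_permutation_equivariance(self, rng):
        entries = rng.normal(size=(5, 3, 6))
        arc = tg.GradientArchive(entries=entries, mode=tg.MODE_CHANNEL)
        perm = rng.permutation(6)
        arc_p = tg.GradientArchive(entries=entries[:, :, perm], mode=tg.MODE_CHANNEL)
        for method in tg.GRAD_METHODS:
            base = tg.grad_scores(arc, method)
            permed = tg.grad_scores(arc_p, method)
            np.testing.assert_allclose(permed.scores, base.scores[perm], rtol=1e-12)
            # rankings relabel consistently: scores along both rankings agree
            np.testing.assert_allclose(
                permed.scores[permed.ranking], base.scores[base.ranking], rtol=1e-12
            )


class TestAhpAggregate:
    def _cell_estimate(self, cells):
        cells = np.asarray(cells, dtype=float)
        return tg.ImportanceEstimate(
            scores=cells.ravel(),
            method="grad_auc",
            feature_axis=AXIS_CELL,
            feature_shape=cells.shape,
        )

    def test_column_means(self):
        est = tg.ahp_aggregate(self._cell_estimate([[1.0, 0.0], [3.0, 0.0]]), 2, 2)
        np.testing.assert_allclose(est.scores, [2.0, 0.0])
        np.testing.assert_array_equal(est.ranking, [0, 1])
        assert est.feature_axis == AXIS_CHANNEL

    def test_uniform_cells(self):
        est = tg.ahp_aggregate(self._cell_estimate(np.full((3, 4), 0.5)), 3, 4)
        assert np.allclose(est.scores, 0.5)
        np.testing.assert_array_equal(est.ranking, np.arange(4))

    def test_scaling_linearity(self, rng):
        cells = np.abs(rng.normal(size=(5, 3)))
        base = tg.ahp_aggregate(self._cell_estimate(cells), 5, 3)
        scaled = cells.copy()
        scaled[:, 1] *= 7.0
        out = tg.ahp_aggregate(self._cell_estimate(scaled), 5, 3)
        assert out.scores[1] == pytest.approx(7.0 * base.scores[1])
        assert out.scores[0] == pytest.approx(base.scores[0])

    def test_non_rectangular_rejected(self):
        est = tg.ImportanceEstimate(
            scores=np.ones(7), method="grad_auc", feature_axis=AXIS_CELL
        )
        with pytest.raises(tg.DimensionError):
            tg.ahp_aggregate(est, 2, 3)


class TestProperties:
    @given(
        v=hnp.arrays(np.float64, st.integers(2, 30), elements=finite_floats),
        w_seed=st.integers(0, 2**16),
        a=st.floats(-100, 100),
        b=st.floats(-100, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_auc_linearity(self, v, w_seed, a, b):
        w = np.random.default_rng(w_seed).uniform(-1e6, 1e6, size=v.size)
        lhs = tg.auc(a * v + b * w)
        rhs = a * tg.auc(v) + b * tg.auc(w)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-3)

    @given(v=hnp.arrays(np.float64, st.integers(2, 50), elements=finite_floats))
    @settings(max_examples=100, deadline=None)
    def test_roc_telescopes_to_last_value(self, v):
        assert np.sum(tg.roc(v)) == pytest.approx(v[-1], rel=1e-9, abs=1e-6)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=30, deadline=None)
    def test_ranking_validity(self, seed):
        rng = np.random.default_rng(seed)
        arc = tg.GradientArchive(
            entries=rng.normal(size=(4, 3, 8)), mode=tg.MODE_CHANNEL
        )
        for method in tg.GRAD_METHODS:
            est = tg.grad_scores(arc, method)
            assert sorted(est.ranking.tolist()) == list(range(8))  # bijective
            ordered = est.scores[est.ranking]
            assert np.all(np.diff(ordered) <= 0)  # non-increasing


class TestSaveEstimate:
    def test_csv_round_trip(self, tmp_path, rng):
        import pandas as pd

        arc = tg.GradientArchive(entries=rng.normal(size=(3, 2, 4)), mode=tg.MODE_CHANNEL)
        est = tg.grad_scores(arc, "grad_auc")
        path = tg.save_estimate(
            est, tmp_path / "scores.csv", channel_names=list("abcd"), run_seed=3
        )
        frame = pd.read_csv(path)
        assert list(frame.columns) == [
            "feature_id",
            "feature_label",
            "method",
            "score",
            "rank",
            "run_seed",
        ]
        np.testing.assert_allclose(frame["score"], est.scores)
        assert frame.loc[frame["rank"] == 0, "feature_id"].item() == est.ranking[0]
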