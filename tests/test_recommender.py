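"""Response model: conversion, features, prediction, training, NDCG, SSE."""

import math

import numpy as np
import pandas as pd
import pytest

from pathwaydr import (
    CellLineFeatures,
    DrugResponseMatrix,
    PathwayActivityMatrix,
    RecommenderModel,
    compute_cellline_features,
    convert_ic50,
    evaluate_ranking,
    ndcg,
    predict,
    sse_loss,
    train,
)

from _oracles import ndcg_brute, sse_brute
from conftest import random_profile_frame


class TestConvertIc50:
    @pytest.mark.parametrize(
        "value,scale,expected",
        [
            (0.0, "ln", 0.0),
            (1.0, "linear", 0.0),
            (math.log(10.0), "ln", -1.0),
            (2.0, "log10", -2.0),
            (0.001, "linear", 3.0),
        ],
    )
    def test_scalar_conversions(self, value, scale, expected):
        assert convert_ic50(value, scale) == pytest.approx(expected, abs=1e-12)

    def test_frame_conversion_preserves_nan(self):
        df = pd.DataFrame([[math.log(10.0), np.nan]], index=["d"], columns=["a", "b"])
        out = convert_ic50(df, "ln")
        assert out.loc["d", "a"] == pytest.approx(-1.0)
        assert np.isnan(out.loc["d", "b"])

    def test_nonpositive_linear_rejected(self):
        with pytest.raises(ValueError):
            convert_ic50(np.array([1.0, 0.0]), "linear")


class TestCellLineFeatures:
    def test_diagonal_affine_and_anticorrelation(self, rng):
        y = rng.normal(size=6)
        df = pd.DataFrame(
            {"u": y, "v": 2 * y + 3, "w": -y}, index=[f"pw{i}" for i in range(6)]
        )
        feats = compute_cellline_features(PathwayActivityMatrix(data=df))
        assert feats.data.loc["u", "u"] == pytest.approx(1.0)
        assert feats.data.loc["u", "v"] == pytest.approx(1.0)
        assert feats.data.loc["u", "w"] == pytest.approx(-1.0)
        assert feats.d == 3

    def test_zero_variance_cell_line_named_in_error(self, rng):
        df = random_profile_frame(rng)
        df["flatline"] = 5.0
        with pytest.raises(ValueError, match="flatline"):
            compute_cellline_features(PathwayActivityMatrix(data=df))


def _model(mu, b_drug, b_cell, q, w, f, feature_ids):
    return RecommenderModel(
        mu=mu,
        drug_bias=pd.Series(b_drug),
        cell_bias=pd.Series(b_cell),
        drug_latent=pd.DataFrame(np.asarray(q), index=list(b_drug)),
        projection=np.asarray(w, dtype=float),
        f=f,
        feature_ids=feature_ids,
    )


class TestPredict:
    def _features(self, rng, n_cells=4):
        ids = [f"c{j}" for j in range(n_cells)]
        x = np.clip(rng.normal(0, 0.3, size=(n_cells, n_cells)), -1, 1)
        np.fill_diagonal(x, 1.0)
        return CellLineFeatures(data=pd.DataFrame(x, index=ids, columns=ids))

    def test_all_zero_model_predicts_mu(self, rng):
        feats = self._features(rng)
        m = _model(2.5, {"d1": 0.0, "d2": 0.0}, {c: 0.0 for c in feats.cellline_ids},
                   np.zeros((2, 2)), np.zeros((4, 2)), 2, feats.feature_ids)
        out = predict(m, feats)
        np.testing.assert_allclose(out.data.to_numpy(), 2.5)

    def test_f_zero_is_bias_only(self, rng):
        feats = self._features(rng)
        b_d = {"d1": 0.5, "d2": -1.0}
        b_c = {c: 0.1 * j for j, c in enumerate(feats.cellline_ids)}
        m = _model(1.0, b_d, b_c, np.zeros((2, 0)), np.zeros((4, 0)), 0, feats.feature_ids)
        out = predict(m, feats)
        for i, d in enumerate(b_d):
            for c in feats.cellline_ids:
                assert out.data.loc[d, c] == pytest.approx(1.0 + b_d[d] + b_c[c])

    def test_matches_elementwise_hand_evaluation(self, rng):
        feats = self._features(rng)
        n_d, f = 3, 2
        b_d = {f"d{i}": float(rng.normal()) for i in range(n_d)}
        b_c = {c: float(rng.normal()) for c in feats.cellline_ids}
        q = rng.normal(size=(n_d, f))
        w = rng.normal(size=(feats.d, f))
        m = _model(0.7, b_d, b_c, q, w, f, feats.feature_ids)
        out = predict(m, feats)
        for i, d in enumerate(b_d):
            for u, c in enumerate(feats.cellline_ids):
                x_u = feats.data.loc[c].to_numpy()
                p_u = x_u @ w
                manual = 0.7 + b_d[d] + b_c[c] + float(q[i] @ p_u)
                assert out.data.loc[d, c] == pytest.approx(manual, abs=1e-12)

    def test_gauge_invariance_scaling_w_against_q(self, rng):
        feats = self._features(rng)
        q = rng.normal(size=(2, 2))
        w = rng.normal(size=(4, 2))
        b_d = {"d1": 0.2, "d2": 0.3}
        b_c = {c: 0.0 for c in feats.cellline_ids}
        m1 = _model(0.0, b_d, b_c, q, w, 2, feats.feature_ids)
        m2 = _model(0.0, b_d, b_c, q / 2.0, w * 2.0, 2, feats.feature_ids)
        np.testing.assert_allclose(
            predict(m1, feats).data.to_numpy(), predict(m2, feats).data.to_numpy(), atol=1e-12
        )

    def test_shape_mismatch_rejected(self, rng):
        feats = self._features(rng, n_cells=4)
        m = _model(0.0, {"d1": 0.0}, {c: 0.0 for c in feats.cellline_ids},
                   np.zeros((1, 2)), np.zeros((5, 2)), 2, [f"x{i}" for i in range(5)])
        with pytest.raises(ValueError):
            predict(m, feats)


class TestTrain:
    def test_recovers_noise_free_generating_model(self, cellline_features, fixture_config,
                                                  response_and_truth):
        response, truth = response_and_truth
        model = train(response, cellline_features, f=fixture_config.f_true, seed=5)
        got = predict(model, cellline_features).data.to_numpy()
        want = predict(truth, cellline_features).data.to_numpy()
        rmse = float(np.sqrt(np.mean((got - want) ** 2)))
        assert rmse < 1e-2

    def test_constant_matrix_fits_exactly(self, rng):
        cells = [f"c{j}" for j in range(5)]
        feats = CellLineFeatures(
            data=pd.DataFrame(np.eye(5), index=cells, columns=cells)
        )
        obs = DrugResponseMatrix(
            data=pd.DataFrame(np.full((3, 5), 4.2), index=["d1", "d2", "d3"], columns=cells)
        )
        model = train(obs, feats, f=2, seed=0)
        assert model.loss_trace[-1] < 1e-10
        np.testing.assert_allclose(predict(model, feats).data.to_numpy(), 4.2, atol=1e-4)

    def test_loss_trace_monotone_non_increasing(self, cellline_features, response_and_truth):
        response, _ = response_and_truth
        model = train(response, cellline_features, f=3, seed=2, max_epochs=400)
        trace = np.asarray(model.loss_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_masked_cells_never_influence_the_fit(self, cellline_features, rng):
        cells = cellline_features.cellline_ids
        base = rng.normal(size=(6, len(cells)))
        mask = rng.random(size=base.shape) < 0.25
        a = base.copy()
        a[mask] = np.nan
        b = base + np.where(mask, 100.0, 0.0)  # junk only where masked
        b[mask] = np.nan
        drugs = [f"d{i}" for i in range(6)]
        ma = train(DrugResponseMatrix(data=pd.DataFrame(a, index=drugs, columns=cells)),
                   cellline_features, f=2, seed=9, max_epochs=200)
        mb = train(DrugResponseMatrix(data=pd.DataFrame(b, index=drugs, columns=cells)),
                   cellline_features, f=2, seed=9, max_epochs=200)
        np.testing.assert_array_equal(ma.drug_bias.to_numpy(), mb.drug_bias.to_numpy())
        np.testing.assert_array_equal(ma.projection, mb.projection)
        assert ma.loss_trace == mb.loss_trace

    def test_mu_fixed_to_observed_mean(self, cellline_features, response_and_truth):
        response, _ = response_and_truth
        model = train(response, cellline_features, f=2, seed=1, max_epochs=5)
        assert model.mu == pytest.approx(float(np.nanmean(response.data.to_numpy())))

    def test_empty_observation_rejected(self, cellline_features):
        cells = cellline_features.cellline_ids
        empty = pd.DataFrame(np.nan, index=["d1"], columns=cells)
        with pytest.raises(ValueError):
            train(DrugResponseMatrix(data=empty), cellline_features, f=1, seed=0)


class TestNdcg:
    def test_perfect_ranking_scores_one(self, rng):
        obs = rng.permutation(np.arange(8, dtype=float))
        assert ndcg(obs, obs) == pytest.approx(1.0)

    def test_single_drug_scores_one(self):
        assert ndcg([0.3], [2.0]) == pytest.approx(1.0)

    def test_reversed_two_drug_ranking_matches_brute_force(self):
        # independent hand computation (raw relevances, no shifting):
        # model order puts s=1 first -> DCG = 1/log2(2) + 3/log2(3)
        # ideal order                -> DCG = 3/log2(2) + 1/log2(3)
        got = ndcg([0.0, 1.0], [2.0, 1.0], shift_relevance=False)
        want = (1.0 / math.log2(2) + 3.0 / math.log2(3)) / (
            3.0 / math.log2(2) + 1.0 / math.log2(3)
        )
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(ndcg_brute([0.0, 1.0], [2.0, 1.0], shift=False), abs=1e-12)

    def test_constant_relevance_defined_as_one(self):
        assert ndcg([0.2, 0.9, 0.1], [3.0, 3.0, 3.0]) == pytest.approx(1.0)

    def test_random_vectors_match_oracle_and_stay_in_unit_interval(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 12))
            obs = rng.normal(size=n)  # negative relevances exercised via shift
            pred = rng.normal(size=n)
            got = ndcg(pred, obs)
            assert 0.0 <= got <= 1.0 + 1e-12
            assert got == pytest.approx(ndcg_brute(pred.tolist(), obs.tolist()), abs=1e-12)

    def test_shifted_negative_relevances_keep_unit_range(self, rng):
        obs = np.array([-5.0, -1.0, -3.0])
        assert 0.0 <= ndcg(rng.normal(size=3), obs) <= 1.0


class TestSseLoss:
    def _mk(self, arr, drugs=None, cells=None):
        arr = np.asarray(arr, dtype=float)
        drugs = drugs or [f"d{i}" for i in range(arr.shape[0])]
        cells = cells or [f"c{j}" for j in range(arr.shape[1])]
        return DrugResponseMatrix(data=pd.DataFrame(arr, index=drugs, columns=cells))

    def test_zero_for_exact_predictions(self, rng):
        obs = self._mk(rng.normal(size=(3, 4)))
        loss, resid = sse_loss(obs, obs)
        assert loss == 0.0
        assert resid.abs().max().max() == 0.0

    def test_single_entry_arithmetic(self):
        obs = self._mk([[3.0]])
        pred = self._mk([[1.0]])
        loss, _ = sse_loss(obs, pred)
        assert loss == pytest.approx(2.0)  # (1 / (2*1)) * 2^2

    def test_missing_entries_excluded_matches_brute_force(self, rng):
        arr = rng.normal(size=(3, 3))
        arr[0, 1] = np.nan
        arr[2, 2] = np.nan
        obs = self._mk(arr)
        pred = self._mk(rng.normal(size=(3, 3)))
        loss, _ = sse_loss(obs, pred)
        want = sse_brute(obs.data.to_numpy().tolist(), pred.data.to_numpy().tolist())
        assert loss == pytest.approx(want, abs=1e-12)

    def test_all_missing_rejected(self):
        obs = DrugResponseMatrix(
            data=pd.DataFrame([[np.nan, np.nan]], index=["d"], columns=["a", "b"])
        )
        pred = self._mk([[0.0, 0.0]], drugs=["d"], cells=["a", "b"])
        with pytest.raises(ValueError):
            sse_loss(obs, pred)


def test_leave_one_cellline_out_ranks_held_out_cells_well(response_and_truth, cellline_features):
    """Noise-free model-generated responses: every held-out cell line's
    ranking should be predicted almost perfectly from the remaining panel."""
    from pathwaydr import leave_one_cellline_out

    response, _ = response_and_truth
    scores = leave_one_cellline_out(
        response, cellline_features, f=2, seed=3, max_epochs=300
    )
    assert set(scores.index) == set(response.cellline_ids)
    assert ((scores >= 0) & (scores <= 1)).all()
    assert scores.mean() > 0.9


def test_evaluate_ranking_reports_per_cellline_mean_and_sse(response_and_truth, cellline_features):
    response, truth = response_and_truth
    predicted = predict(truth, cellline_features)
    ev = evaluate_ranking(response, predicted)
    assert set(ev.per_cellline.index) == set(response.cellline_ids)
    assert ev.mean_ndcg == pytest.approx(1.0)  # noise-free generator
    assert ev.sse == pytest.approx(0.0, abs=1e-20)
    assert 0.0 <= ev.pooled_ndcg <= 1.0
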