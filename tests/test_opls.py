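import numpy as np
import pandas as pd
import pytest

from basketpls.datatypes import FeatureMatrix, ResponseVector
from basketpls.opls import (
    ModelError,
    OplsModel,
    _fit_opls_arrays,
    compute_vip,
    cross_validate_q2,
    fit_opls,
    fit_pls1,
    pls1_predict,
    predict,
    scores_projection,
)
from basketpls.simulate import default_spec, generate_rppa_like

from conftest import curate, make_linear_dataset


def autoscaled(x):
    from basketpls.curation import autoscale
    return autoscale(x)


class TestPls1:
    def test_rank_one_structure_fully_explained(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal(12)
        p = rng.standard_normal(4)
        X = np.outer(t, p)
        ids = [f"s{i}" for i in range(12)]
        x = FeatureMatrix(pd.DataFrame(X, index=ids, columns=list("abcd")))
        y = ResponseVector(pd.Series(
            0.5 + 0.3 * (t - t.mean()) / np.abs(t).max(), index=ids))
        fit = fit_pls1(x, y, 1)
        yhat = pls1_predict(fit, x)
        r2 = 1 - np.sum((yhat - y.auc) ** 2) / np.sum((y.auc - y.auc.mean()) ** 2)
        assert r2 > 1 - 1e-10

    def test_constant_response_error(self):
        x, y, _ = make_linear_dataset(10, 3, seed=1)
        flat = ResponseVector(pd.Series(0.5, index=y.sample_ids))
        with pytest.raises(ModelError, match="zero-variance"):
            fit_pls1(x, flat, 1)

    def test_full_components_match_least_squares(self):
        # with as many components as (full-rank) features, PLS1 spans the
        # whole column space and reproduces the OLS fit
        x, y, _ = make_linear_dataset(10, 3, seed=3, noise_sd=0.3)
        fit = fit_pls1(x, y, n_components=3)
        X = x.values.to_numpy()
        Xc = X - X.mean(axis=0)
        yc = y.auc.to_numpy() - y.auc.mean()
        beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        ols = y.auc.mean() + Xc @ beta
        np.testing.assert_allclose(pls1_predict(fit, x), ols, atol=1e-8)

    def test_unit_norm_weights(self):
        x, y, _ = make_linear_dataset(15, 6, seed=4, noise_sd=0.5)
        fit = fit_pls1(x, y, 3)
        np.testing.assert_allclose(np.linalg.norm(fit["W"], axis=1), 1.0, atol=1e-10)


class TestOplsFit:
    def test_no_orthogonal_structure_keeps_zero_components(self):
        x, y, truth = generate_rppa_like(
            default_spec(seed=5, orthogonal_strength=0.0, missing_fraction=0.0))
        scaled, params, y = curate(x, y)
        model = fit_opls(scaled, y, scaling=params, seed=0)
        assert model.n_orthogonal == 0

    def test_confounded_data_retains_an_orthogonal_component(self):
        # majority behavior over seeds: a strong response-orthogonal factor
        # is picked up and improves Q2Y
        from basketpls.simulate import confounded_spec
        kept = 0
        improved = 0
        n_seeds = 10
        for seed in range(n_seeds):
            x, y, _ = generate_rppa_like(confounded_spec(seed=seed))
            scaled, params, y = curate(x, y)
            model = fit_opls(scaled, y, scaling=params, seed=0)
            if model.n_orthogonal >= 1:
                kept += 1
                q2_path = model.stats["Q2Y_path"]
                improved += q2_path[model.n_orthogonal] > q2_path[0]
        assert kept > n_seeds / 2
        assert improved == kept

    def test_sample_permutation_leaves_components_unchanged(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 8))
        yv = rng.uniform(size=20)
        Xc = X - X.mean(axis=0)
        yc = yv - yv.mean()
        fit_a = _fit_opls_arrays(Xc, yc, 1)
        perm = rng.permutation(20)
        fit_b = _fit_opls_arrays(Xc[perm], yc[perm], 1)
        np.testing.assert_allclose(fit_a["w"], fit_b["w"], atol=1e-10)
        np.testing.assert_allclose(fit_a["p"], fit_b["p"], atol=1e-10)
        assert fit_a["b"] == pytest.approx(fit_b["b"], abs=1e-10)

    def test_too_few_samples_for_folds_error(self):
        x, y, _ = make_linear_dataset(5, 3, seed=0)
        with pytest.raises(ModelError):
            fit_opls(x, y, folds=7)

    def test_orthogonal_scores_uncorrelated_with_response(self, default_model,
                                                          default_dataset):
        y = default_dataset["y"].auc.to_numpy()
        for k in range(default_model.n_orthogonal):
            t_o = default_model.ortho_scores[:, k]
            assert abs(np.corrcoef(t_o, y)[0, 1]) < 1e-6

    def test_weight_orthogonality_invariants(self, default_model):
        assert np.linalg.norm(default_model.weights) == pytest.approx(1.0, abs=1e-10)
        for w_o in default_model.ortho_weights:
            assert abs(default_model.weights @ w_o) < 1e-8

    def test_stats_ranges(self, default_model):
        s = default_model.stats
        assert 0 <= s["R2Y"] <= 1
        assert s["Q2Y"] <= 1


class TestPredict:
    def test_training_matrix_reproduces_fitted_values(self, default_model,
                                                      default_dataset):
        d = default_dataset
        raw = d["params"].inverse_transform(d["scaled"].values)
        fitted = default_model.y_mean + default_model.coef * default_model.scores
        got = predict(default_model, FeatureMatrix(raw))
        np.testing.assert_allclose(got.to_numpy(), fitted, atol=1e-8)

    def test_sample_at_feature_means_predicts_mean_response(self, default_model,
                                                            default_dataset):
        d = default_dataset
        mean_row = d["params"].mean.to_frame().T
        mean_row.index = ["mean_sample"]
        got = predict(default_model, FeatureMatrix(mean_row))
        assert got.iloc[0] == pytest.approx(default_model.y_mean, abs=1e-10)

    def test_orthogonal_loading_direction_is_invisible(self):
        # displacing a sample along p_o must not change its prediction
        from basketpls.simulate import confounded_spec
        x, y, _ = generate_rppa_like(confounded_spec(seed=3))
        scaled, params, y = curate(x, y)
        model = fit_opls(scaled, y, scaling=params, seed=0)
        assert model.n_orthogonal >= 1
        raw = params.inverse_transform(scaled.values)
        base = FeatureMatrix(raw.iloc[[0]])
        p_o_raw = model.ortho_loadings[0] * params.std.to_numpy()
        for c in (-3.0, 1.0, 10.0):
            shifted = FeatureMatrix(base.values + c * p_o_raw)
            d = abs(predict(model, shifted).iloc[0] - predict(model, base).iloc[0])
            assert d < 1e-8

    def test_missing_feature_listed_in_error(self, default_model, default_dataset):
        raw = default_dataset["params"].inverse_transform(
            default_dataset["scaled"].values)
        broken = FeatureMatrix(raw.drop(columns=[default_model.feature_ids[0]]))
        with pytest.raises(ModelError, match=default_model.feature_ids[0]):
            predict(default_model, broken)


class TestCrossValidation:
    def test_exact_linear_response_gives_high_q2(self):
        x, y, _ = make_linear_dataset(21, 3, seed=1, noise_sd=0.0, latent=True)
        scaled, params, y = curate(x, y, detection=0.01)
        assert cross_validate_q2(scaled, y, 0, folds=7, seed=0) > 0.99

    def test_shuffled_response_gives_nonpositive_median_q2(self):
        x, y, _ = make_linear_dataset(21, 10, seed=2, noise_sd=0.0)
        scaled, params, _ = curate(x, y, detection=0.01)
        rng = np.random.default_rng(0)
        q2s = []
        for _ in range(20):
            y_perm = ResponseVector(pd.Series(
                rng.permutation(y.auc.to_numpy()), index=y.sample_ids))
            q2s.append(cross_validate_q2(scaled, y_perm, 0, folds=7, seed=1))
        assert np.median(q2s) <= 0

    def test_same_seed_is_deterministic(self, default_dataset):
        d = default_dataset
        a = cross_validate_q2(d["scaled"], d["y"], 1, folds=7, seed=9)
        b = cross_validate_q2(d["scaled"], d["y"], 1, folds=7, seed=9)
        assert a == b


class TestVip:
    def test_symmetric_weights_give_unit_vip(self):
        # equal-weight one-component model: every VIP is exactly 1
        rng = np.random.default_rng(0)
        n, p = 24, 4
        t = rng.standard_normal(n)
        X = np.outer(t, np.ones(p))
        ids = [f"s{i}" for i in range(n)]
        x = FeatureMatrix(pd.DataFrame(X, index=ids, columns=list("abcd")))
        span = t.max() - t.min()
        y = ResponseVector(pd.Series(0.02 + 0.96 * (t - t.min()) / span, index=ids))
        model = fit_opls(x, y, max_orthogonal=0, folds=6, seed=0)
        vip = compute_vip(model)
        np.testing.assert_allclose(vip["VIP"], 1.0, atol=1e-8)

    def test_degenerate_two_feature_model(self):
        # w = (1, 0) in a one-component model gives VIP = (sqrt(2), 0)
        rng = np.random.default_rng(1)
        n = 20
        y_raw = rng.uniform(0.1, 0.9, size=n)
        yc = y_raw - y_raw.mean()
        noise = rng.standard_normal(n)
        ortho = noise - (noise @ yc) / (yc @ yc) * yc  # exactly y-orthogonal
        X = np.column_stack([yc, ortho])
        ids = [f"s{i}" for i in range(n)]
        x = FeatureMatrix(pd.DataFrame(X, index=ids, columns=["sig", "noise"]))
        y = ResponseVector(pd.Series(y_raw, index=ids))
        model = fit_opls(x, y, max_orthogonal=0, folds=5, seed=0)
        vip = compute_vip(model)
        np.testing.assert_allclose(vip["VIP"], [np.sqrt(2.0), 0.0], atol=1e-8)

    def test_mean_squared_vip_is_one_across_random_fits(self):
        for seed in range(10):
            x, y, _ = generate_rppa_like(default_spec(seed=seed))
            scaled, params, y = curate(x, y)
            model = fit_opls(scaled, y, scaling=params, seed=0)
            vip = compute_vip(model)
            assert abs((vip["VIP"] ** 2).mean() - 1.0) < 1e-8


class TestScoresProjection:
    def test_training_scores_recovered(self, default_model, default_dataset):
        d = default_dataset
        raw = d["params"].inverse_transform(d["scaled"].values)
        proj = scores_projection(default_model, FeatureMatrix(raw))
        np.testing.assert_allclose(proj["t"], default_model.scores, atol=1e-10)
        for k in range(default_model.n_orthogonal):
            np.testing.assert_allclose(proj[f"t_o{k + 1}"],
                                       default_model.ortho_scores[:, k], atol=1e-10)

    def test_duplicated_rows_give_identical_scores(self, default_model,
                                                   default_dataset):
        d = default_dataset
        raw = d["params"].inverse_transform(d["scaled"].values)
        dup = pd.concat([raw.iloc[[2]], raw.iloc[[2]].set_axis(["copy"])])
        proj = scores_projection(default_model, FeatureMatrix(dup))
        np.testing.assert_allclose(proj.iloc[0], proj.iloc[1], atol=1e-12)


class TestSerialization:
    def test_json_round_trip_predictions_bit_stable(self, default_model,
                                                    default_dataset, tmp_path):
        d = default_dataset
        raw = d["params"].inverse_transform(d["scaled"].values)
        path = tmp_path / "model.json"
        default_model.to_json(path)
        loaded = OplsModel.from_json(path)
        a = predict(default_model, FeatureMatrix(raw))
        b = predict(loaded, FeatureMatrix(raw))
        assert (a == b).all()
        assert loaded.stats["Q2Y"] == default_model.stats["Q2Y"]


class TestOplsLimit:
    def test_zero_orthogonal_equals_pls1(self):
        # O-PLS with no orthogonal filtering is exactly one-component PLS1
        for seed in range(5):
            x, y, _ = make_linear_dataset(15, 8, seed=seed, noise_sd=0.5)
            scaled, params, y = curate(x, y, detection=0.01)
            model = fit_opls(scaled, y, max_orthogonal=0, folds=5, seed=0,
                             scaling=params)
            raw = params.inverse_transform(scaled.values)
            opls_pred = predict(model, FeatureMatrix(raw))
            pls_fit = fit_pls1(scaled, y, 1)
            pls_pred = pls1_predict(pls_fit, scaled)
            np.testing.assert_allclose(opls_pred.to_numpy(), pls_pred.to_numpy(),
                                       atol=1e-8)
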