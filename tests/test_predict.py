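import numpy as np
import pandas as pd
import pytest

from crossmeth import ValidationError, fit_linear_probe, fit_probe_models, fit_svr_probe, predict_matrix
from crossmeth.predict import (
    fit_multiprobe,
    load_model_set,
    predict_linear_probe,
    predict_multiprobe,
    save_model_set,
    select_multiprobe_predictors,
    select_target_probes_for_multiprobe,
)

from conftest import make_beta


class TestLinearFit:
    @pytest.mark.parametrize(
        "x,y,intercept,slope",
        [
            ([0.1, 0.2, 0.3], [0.25, 0.45, 0.65], 0.05, 2.0),
            ([0.1, 0.4, 0.8], [0.1, 0.4, 0.8], 0.0, 1.0),
            ([0.0, 1.0, 0.0, 1.0], [0.2, 0.8, 0.3, 0.7], 0.25, 0.5),
        ],
    )
    def test_known_fits(self, x, y, intercept, slope):
        m = fit_linear_probe(x, y)
        assert m.intercept == pytest.approx(intercept, abs=1e-12)
        assert m.slope == pytest.approx(slope, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(3, 12)
            x = rng.random(n)
            y = rng.random(n)
            if np.std(x) < 1e-3:
                continue
            m = fit_linear_probe(x, y)
            coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), x]), y, rcond=None)
            assert m.intercept == pytest.approx(coef[0], abs=1e-10)
            assert m.slope == pytest.approx(coef[1], abs=1e-10)

    def test_constant_x_falls_back_to_mean(self):
        m = fit_linear_probe([0.5, 0.5, 0.5], [0.2, 0.4, 0.6])
        assert m.flag == "constant_x"
        assert m.predict(0.9) == pytest.approx(0.4)

    def test_too_few_pairs_flagged(self):
        m = fit_linear_probe([0.1, np.nan, 0.3], [0.2, 0.5, np.nan])
        assert m.flag == "insufficient_data"
        assert np.isnan(m.predict(0.5))

    def test_pairwise_complete_fitting(self):
        m = fit_linear_probe([0.1, 0.2, np.nan, 0.3], [0.25, 0.45, 0.9, 0.65])
        assert m.n_obs == 3
        assert m.slope == pytest.approx(2.0, abs=1e-12)

    def test_prediction_outside_unit_interval_is_not_clamped(self):
        m = fit_linear_probe([0.3, 0.4, 0.5], [0.85, 1.0, 0.8])
        m.intercept, m.slope = 0.9, 1.5  # documented extrapolation behaviour
        assert predict_linear_probe(m, 0.5) == pytest.approx(1.65)


class TestSvrFit:
    def test_constant_target_predicts_the_constant(self):
        m = fit_svr_probe([0.1, 0.5, 0.9], [0.5, 0.5, 0.5])
        assert m.flag == "constant_y"
        np.testing.assert_allclose(m.predict([0.0, 0.3, 2.0]), 0.5)

    def test_recovers_a_noisy_line(self, rng):
        x = rng.uniform(0.1, 0.9, 30)
        y = 0.1 + 0.8 * x + rng.normal(0, 0.01, 30)
        m = fit_svr_probe(x, y)
        assert m.predict(0.5) == pytest.approx(0.5, abs=0.05)

    def test_predictions_confined_to_training_target_range(self, rng):
        x = rng.uniform(0, 1, 25)
        y = np.clip(0.2 + 0.5 * x + rng.normal(0, 0.05, 25), 0, 1)
        m = fit_svr_probe(x, y)
        queries = np.array([-50.0, -1.0, 0.0, 0.5, 1.0, 2.0, 50.0])
        pred = m.predict(queries)
        assert (pred >= m.y_min).all() and (pred <= m.y_max).all()

    def test_missing_inputs_give_missing_predictions(self):
        m = fit_svr_probe([0.1, 0.5, 0.9, 0.3], [0.2, 0.6, 0.8, 0.4])
        out = m.predict([0.5, np.nan])
        assert not np.isnan(out[0]) and np.isnan(out[1])


class TestProbeModelSets:
    def test_identity_data_gives_identity_models(self, small_pair):
        X, _, _, _ = small_pair
        ms = fit_probe_models(X, X, "LM")
        slopes = np.array([m.slope for m in ms.models.values() if m.flag is None])
        intercepts = np.array([m.intercept for m in ms.models.values() if m.flag is None])
        np.testing.assert_allclose(slopes, 1.0, atol=1e-8)
        np.testing.assert_allclose(intercepts, 0.0, atol=1e-8)

    def test_pairwise_complete_per_probe(self):
        X = make_beta([[0.1], [0.2], [np.nan], [0.4], [0.5]])
        Y = make_beta([[0.2], [0.4], [0.6], [0.8], [1.0]])
        ms = fit_probe_models(X, Y, "LM")
        assert ms.models["cg00001"].n_obs == 4

    def test_svr_shares_probe_keys_with_lm(self, small_pair):
        X, Y, _, _ = small_pair
        sub = X.probe_ids[:10]
        lm = fit_probe_models(X.select(probes=sub), Y.select(probes=sub), "LM")
        svr = fit_probe_models(X.select(probes=sub), Y.select(probes=sub), "SVR")
        assert list(lm.models) == list(svr.models)

    def test_vectorized_lm_agrees_with_per_probe_fit(self, small_pair):
        X, Y, _, _ = small_pair
        ms = fit_probe_models(X, Y, "LM")
        for pid in X.probe_ids[::17]:
            single = fit_linear_probe(X.data[pid].to_numpy(), Y.data[pid].to_numpy(), pid)
            assert ms.models[pid].slope == pytest.approx(single.slope, abs=1e-10)
            assert ms.models[pid].intercept == pytest.approx(single.intercept, abs=1e-10)


class TestPredictMatrix:
    def test_identity_models_reproduce_input(self, small_pair):
        X, _, _, _ = small_pair
        ms = fit_probe_models(X, X, "LM")
        res = predict_matrix(ms, X)
        np.testing.assert_allclose(res.values.to_numpy(), X.values, atol=1e-8)

    def test_missing_surrogate_gives_missing_prediction(self):
        X = make_beta([[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]])
        ms = fit_probe_models(X, X, "LM")
        X_new = make_beta([[np.nan, 0.5]], samples=["Z"])
        res = predict_matrix(ms, X_new)
        assert np.isnan(res.values.iloc[0, 0]) and not np.isnan(res.values.iloc[0, 1])

    def test_unknown_probe_is_an_error(self, small_pair):
        X, _, _, _ = small_pair
        ms = fit_probe_models(X.select(probes=X.probe_ids[:5]), X.select(probes=X.probe_ids[:5]), "LM")
        with pytest.raises(ValidationError, match="without a fitted model"):
            predict_matrix(ms, X.select(probes=X.probe_ids[:6]))

    def test_out_of_range_lm_predictions_counted(self):
        X = make_beta([[0.3], [0.4], [0.5]])
        Y = make_beta([[0.4], [0.6], [0.8]])  # slope 2
        ms = fit_probe_models(X, Y, "LM")
        res = predict_matrix(ms, make_beta([[0.95]], samples=["Z"]))
        assert res.values.iloc[0, 0] > 1.0
        assert res.n_out_of_range == 1

    def test_svr_predictions_within_training_ranges(self, small_pair, rng):
        X, Y, _, _ = small_pair
        sub = X.probe_ids[:15]
        ms = fit_probe_models(X.select(probes=sub), Y.select(probes=sub), "SVR")
        X_new = make_beta(rng.random((5, 15)), probes=sub)
        res = predict_matrix(ms, X_new)
        for pid in sub:
            lo, hi = ms.models[pid].training_y_range
            col = res.values[pid]
            assert (col >= lo - 1e-12).all() and (col <= hi + 1e-12).all()

    def test_prediction_equivariant_under_sample_reordering(self, small_pair, rng):
        X, Y, _, _ = small_pair
        ms = fit_probe_models(X, Y, "LM")
        order = list(rng.permutation(X.sample_ids))
        res_a = predict_matrix(ms, X).values.loc[order]
        res_b = predict_matrix(ms, X.select(order)).values
        pd.testing.assert_frame_equal(res_a, res_b)


class TestSerialization:
    @pytest.mark.parametrize("method", ["LM", "SVR"])
    def test_round_trip_preserves_predictions(self, small_pair, tmp_path, method):
        X, Y, _, _ = small_pair
        sub = X.probe_ids[:8]
        ms = fit_probe_models(X.select(probes=sub), Y.select(probes=sub), method)
        save_model_set(ms, tmp_path / "model.json")
        back = load_model_set(tmp_path / "model.json")
        a = predict_matrix(ms, X.select(probes=sub)).values
        b = predict_matrix(back, X.select(probes=sub)).values
        pd.testing.assert_frame_equal(a, b)

    def test_multiprobe_round_trip(self, small_pair, tmp_path):
        X, Y, _, _ = small_pair
        targets = Y.probe_ids[:4]
        ms = fit_multiprobe(X, Y, targets, k=3)
        save_model_set(ms, tmp_path / "model.json")
        back = load_model_set(tmp_path / "model.json")
        a = predict_multiprobe(ms, X).values
        b = predict_multiprobe(back, X).values
        pd.testing.assert_frame_equal(a, b)


class TestMultiProbe:
    def test_k1_reduces_to_single_probe_lm_exactly(self, small_pair):
        X, Y, _, _ = small_pair
        targets = Y.probe_ids[:10]
        ms = fit_multiprobe(X, Y, targets, k=1)
        for pid in targets:
            lm = fit_linear_probe(X.data[pid].to_numpy(), Y.data[pid].to_numpy(), pid)
            model = ms.models[pid]
            assert model.predictor_ids == [pid]
            assert model.intercept == lm.intercept  # bitwise identical
            assert model.coefs[0] == lm.slope

    def test_duplicated_target_probe_is_selected_second(self, rng):
        n = 20
        base = rng.random(n)
        other = rng.random(n)
        X = make_beta(np.column_stack([base, other, 0.99 * base + 0.005]),
                      probes=["cgA", "cgB", "cgC"])
        y = pd.Series(base, index=X.sample_ids, name="cgA")
        sel = select_multiprobe_predictors(X, y, k=2)
        assert sel == ["cgA", "cgC"]

    def test_correlation_tie_breaks_lexicographically(self):
        base = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        X = make_beta(
            np.column_stack([base, base, base]), probes=["cgT", "cgZ", "cgB"]
        )
        y = pd.Series(base, index=X.sample_ids, name="cgT")
        sel = select_multiprobe_predictors(X, y, k=2)
        assert sel == ["cgT", "cgB"]

    def test_exact_two_predictor_structure_has_zero_residuals(self, rng):
        n = 15
        x1 = rng.random(n)
        x2 = rng.random(n)
        y = np.clip(0.5 * x1 + 0.5 * x2, 0, 1)
        X = make_beta(np.column_stack([x1, x2]), probes=["cgA", "cgB"])
        Y = make_beta(y[:, None], probes=["cgA"])
        ms = fit_multiprobe(X, Y, ["cgA"], k=2)
        pred = predict_multiprobe(ms, X).values["cgA"].to_numpy()
        np.testing.assert_allclose(pred, y, atol=1e-10)

    def test_overparameterized_k_rejected(self, small_pair):
        X, Y, _, _ = small_pair
        with pytest.raises(ValidationError, match="overparameterized"):
            fit_multiprobe(X, Y, Y.probe_ids[:1], k=X.n_samples - 1)

    def test_collinear_predictors_dropped_with_refit(self, rng):
        n = 12
        x1 = rng.random(n)
        X = make_beta(np.column_stack([x1, x1, rng.random(n)]), probes=["cgA", "cgAcopy", "cgB"])
        Y = make_beta(np.clip(0.3 + 0.5 * x1, 0, 1)[:, None], probes=["cgA"])
        ms = fit_multiprobe(X, Y, ["cgA"], k=2)
        model = ms.models["cgA"]
        assert "cgAcopy" not in model.predictor_ids
        pred = predict_multiprobe(ms, X).values["cgA"].to_numpy()
        np.testing.assert_allclose(pred, Y.values[:, 0], atol=1e-8)


class TestTargetProbeSelection:
    def test_same_seed_same_selection(self, small_pair):
        X, Y, _, _ = small_pair
        r2 = pd.Series(0.1, index=Y.probe_ids)
        a = select_target_probes_for_multiprobe(Y, r2, sd_range=(0.0, 1.0), r2_max=0.3, count=10, seed=4)
        b = select_target_probes_for_multiprobe(Y, r2, sd_range=(0.0, 1.0), r2_max=0.3, count=10, seed=4)
        assert a == b and len(a) == 10

    def test_exhausted_pool_returns_all_eligible(self, small_pair):
        X, Y, _, _ = small_pair
        r2 = pd.Series(0.1, index=Y.probe_ids)
        sel = select_target_probes_for_multiprobe(Y, r2, sd_range=(0.1, 0.2), r2_max=0.3, count=10**6, seed=0)
        sd = Y.data.std(ddof=1)
        assert set(sel) == {p for p in Y.probe_ids if 0.1 <= sd[p] <= 0.2}

    def test_sd_bounds_respected(self):
        Y = make_beta(np.column_stack([
            np.linspace(0.1, 0.45, 8),   # sd ~0.12 -> eligible
            np.linspace(0.1, 0.85, 8),   # sd ~0.26 -> excluded
        ]), probes=["cgIn", "cgOut"])
        r2 = pd.Series(0.0, index=Y.probe_ids)
        sel = select_target_probes_for_multiprobe(Y, r2, sd_range=(0.1, 0.2), r2_max=0.3, count=5, seed=0)
        assert sel == ["cgIn"]
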