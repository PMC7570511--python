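"""Feature assembly, ELM, and leave-one-out yield prediction."""

import numpy as np
import pandas as pd
import pytest

from mrbvi.indices import IndexId
from mrbvi.yield_ml import (
    ElmRegressor,
    FoldPreprocessor,
    YieldModelSpec,
    build_features,
    error_band_report,
    fit_elm,
    loo_predict,
    make_model,
)


def _observations(n_plots=20, dates=("d0", "d1"), indices=(IndexId.E8_MRBVI,), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for d in dates:
        for p in range(n_plots):
            rec = {"plot_id": f"p{p:02d}", "date": d, "n_green": 50}
            for idx in indices:
                rec[idx.value] = rng.normal()
            rows.append(rec)
    return pd.DataFrame(rows)


class TestBuildFeatures:
    def test_default_dimensions(self, default_season, default_observations):
        window = sorted(default_season.date_labels)[-8:]
        fm = build_features(default_observations, default_season.yield_table, window)
        assert fm.X.shape == (20, 64)
        assert len(fm.column_labels) == 64
        # index-major, date-minor ordering
        assert fm.column_labels[0] == ("E1_EXR", window[0])
        assert fm.column_labels[7] == ("E1_EXR", window[7])
        assert fm.column_labels[8] == ("E2_NGBDI", window[0])

    def test_minimal_window_single_index(self):
        obs = _observations()
        yields = {f"p{p:02d}": float(p) for p in range(20)}
        fm = build_features(obs, yields, ["d0"], indices=[IndexId.E8_MRBVI])
        assert fm.X.shape == (20, 1)

    def test_row_order_invariance(self):
        obs = _observations(n_plots=6)
        yields = {f"p{p:02d}": float(p) for p in range(6)}
        fm1 = build_features(obs, yields, ["d0", "d1"], indices=[IndexId.E8_MRBVI])
        shuffled = obs.sample(frac=1.0, random_state=3).reset_index(drop=True)
        fm2 = build_features(shuffled, yields, ["d0", "d1"], indices=[IndexId.E8_MRBVI])
        np.testing.assert_array_equal(fm1.X, fm2.X)
        assert fm1.plot_ids == fm2.plot_ids

    def test_missing_yield_names_plot(self):
        obs = _observations(n_plots=4)
        with pytest.raises(ValueError, match="p03"):
            build_features(obs, {f"p{p:02d}": 1.0 for p in range(3)}, ["d0"],
                           indices=[IndexId.E8_MRBVI])

    def test_missing_window_date_rejected(self):
        obs = _observations(n_plots=4)
        with pytest.raises(ValueError, match="d9"):
            build_features(obs, {f"p{p:02d}": 1.0 for p in range(4)}, ["d9"],
                           indices=[IndexId.E8_MRBVI])


class TestElm:
    def test_interpolates_at_full_rank(self):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(15, 5)), rng.normal(size=15)
        model = ElmRegressor(hidden_size=20, alpha=1e-12, random_state=1).fit(X, y)
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse < 1e-6

    def test_fixed_seed_bitwise_identical(self):
        rng = np.random.default_rng(4)
        X, y = rng.normal(size=(12, 6)), rng.normal(size=12)
        a = ElmRegressor(hidden_size=8, random_state=9).fit(X, y)
        b = ElmRegressor(hidden_size=8, random_state=9).fit(X, y)
        np.testing.assert_array_equal(a.W_in_, b.W_in_)
        np.testing.assert_array_equal(a.beta_, b.beta_)

    def test_normal_equation_residual_small(self):
        rng = np.random.default_rng(1)
        X, y = rng.normal(size=(30, 4)), rng.normal(size=30)
        m = ElmRegressor(hidden_size=10, alpha=1e-3, random_state=0).fit(X, y)
        H = m._hidden(X)
        residual = H.T @ (H @ m.beta_ - y) + m.alpha * m.beta_
        assert np.abs(residual).max() < 1e-8

    def test_recovers_random_network_function(self):
        # response generated by a known sigmoid network: ELM should fit it
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 3))
        true = ElmRegressor(hidden_size=5, alpha=1e-6, random_state=77)
        true.fit(X[:10], rng.normal(size=10))  # sets random weights
        true.beta_ = rng.normal(size=5)
        y = true.predict(X)
        model = ElmRegressor(hidden_size=40, alpha=1e-8, random_state=5).fit(X[:300], y[:300])
        rmse = np.sqrt(np.mean((model.predict(X[300:]) - y[300:]) ** 2))
        assert rmse < 0.1 * y.std()

    def test_degenerate_constant_features_rejected(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            ElmRegressor().fit(np.ones((5, 3)), np.arange(5.0))

    def test_fit_elm_spec_wrapper(self):
        rng = np.random.default_rng(2)
        X, y = rng.normal(size=(10, 3)), rng.normal(size=10)
        model = fit_elm(X, y, YieldModelSpec(kind="ELM", seed=3,
                                             hyperparameters={"hidden_size": 7}))
        assert model.W_in_.shape == (7, 3)
        with pytest.raises(ValueError):
            fit_elm(X, y, YieldModelSpec(kind="SVM"))


class TestLooPredict:
    @staticmethod
    def _features(n=12, f=5, seed=0, noise=0.1):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, f))
        y = X[:, 0] * 2.0 + 5.0 + rng.normal(0, noise, size=n)
        return _as_fm(X, y)

    def test_fold_count_equals_n_plots(self):
        fm = self._features(n=20)
        res = loo_predict(fm, YieldModelSpec(kind="ELM", seed=0))
        assert len(res.predictions) == 20

    @pytest.mark.parametrize("kind", ["SVM", "RF", "ELM"])
    def test_constant_response_recovered(self, kind):
        rng = np.random.default_rng(1)
        fm = _as_fm(rng.normal(size=(10, 4)), np.full(10, 7.0))
        res = loo_predict(fm, YieldModelSpec(kind=kind, seed=0))
        # within 5% of the constant (the ELM readout is ridge-shrunk,
        # so its recovery is approximate rather than exact)
        assert res.result.rmse < 0.05 * 7.0

    def test_deterministic_across_runs(self):
        fm = self._features()
        for kind in ("BP", "ELM", "SVM", "RF"):
            a = loo_predict(fm, YieldModelSpec(kind=kind, seed=5))
            b = loo_predict(fm, YieldModelSpec(kind=kind, seed=5))
            np.testing.assert_array_equal(a.predictions.values, b.predictions.values)

    def test_held_out_row_cannot_leak_into_training(self):
        # perturbing the held-out plot's features must leave the model
        # trained for that fold unchanged
        fm = self._features(n=10)
        i = 3
        train = np.arange(10) != i
        prep1 = FoldPreprocessor(True).fit(fm.X[train])
        X2 = fm.X.copy()
        X2[i] += 1e6
        prep2 = FoldPreprocessor(True).fit(X2[train])
        np.testing.assert_array_equal(prep1.col_mean_, prep2.col_mean_)
        np.testing.assert_array_equal(prep1.center_, prep2.center_)
        m1 = make_model(YieldModelSpec(kind="ELM", seed=2)).fit(
            prep1.transform(fm.X[train]), fm.y[train])
        m2 = make_model(YieldModelSpec(kind="ELM", seed=2)).fit(
            prep2.transform(X2[train]), fm.y[train])
        np.testing.assert_array_equal(m1.beta_, m2.beta_)

    def test_nan_cells_are_imputed_fold_wise(self):
        fm = self._features(n=10)
        fm.X[2, 1] = np.nan
        res = loo_predict(fm, YieldModelSpec(kind="ELM", seed=0))
        assert np.all(np.isfinite(res.predictions.values))

    def test_too_few_rows_rejected(self):
        fm = self._features(n=12)
        fm.X, fm.y, fm.plot_ids = fm.X[:2], fm.y[:2], fm.plot_ids[:2]
        with pytest.raises(ValueError):
            loo_predict(fm, YieldModelSpec(kind="SVM"))


def _as_fm(X, y):
    from mrbvi.yield_ml import FeatureMatrix

    n, f = X.shape
    return FeatureMatrix(
        X=X,
        y=np.asarray(y, dtype=np.float64),
        plot_ids=[f"p{i:02d}" for i in range(n)],
        column_labels=[("E8_MRBVI", f"d{j}") for j in range(f)],
    )


class TestErrorBand:
    def test_exact_predictions_all_inside(self):
        assert error_band_report([1.0, 2.0], [1.0, 2.0]) == 0

    def test_single_plot_outside(self):
        M = np.array([10.0, 10.0, 10.0])
        P = np.array([10.0, 12.0, 10.0])  # +20% on one plot
        assert error_band_report(P, M, band=0.15) == 1

    def test_zero_band_counts_any_mismatch(self):
        assert error_band_report([1.0, 2.1], [1.0, 2.0], band=0.0) == 1

    def test_zero_truth_rejected(self):
        with pytest.raises(ZeroDivisionError):
            error_band_report([1.0], [0.0])
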