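"""Plot statistics, regression screens and trajectory metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrbvi.evaluation import (
    linear_r2,
    metrics,
    normalize_series,
    plot_mean_vi,
    stage_screen,
    trajectory_compare,
    trajectory_from_observations,
)
from mrbvi.indices import IndexId, IndexMap
from mrbvi.raster import PlotRoi
from mrbvi.segmentation import GreenMask


def _index_map(values, valid=None):
    values = np.asarray(values, dtype=np.float64)
    valid = np.ones_like(values, bool) if valid is None else valid
    return IndexMap(values=values, valid_mask=valid, index=IndexId.E8_MRBVI)


def _green(mask):
    mask = np.asarray(mask, bool)
    return GreenMask(mask=mask, source=None, green_fraction=float(mask.mean()))


class TestPlotMeanVi:
    def test_constant_field(self):
        imap = _index_map(np.full((10, 10), 0.8))
        mean, n = plot_mean_vi(imap, _green(np.ones((10, 10))), PlotRoi("p", (0, 0, 10, 10)))
        assert mean == pytest.approx(0.8)
        assert n == 100

    def test_non_green_pixels_excluded(self):
        values = np.zeros((4, 4))
        values[:2] = 1.0
        green = np.zeros((4, 4), bool)
        green[:2] = True  # only the value-1 half is green
        mean, n = plot_mean_vi(_index_map(values), _green(green), PlotRoi("p", (0, 0, 4, 4)))
        assert mean == 1.0
        assert n == 8

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=(30, 40))
        green = rng.uniform(size=(30, 40)) > 0.4
        valid = rng.uniform(size=(30, 40)) > 0.1
        roi = PlotRoi("p", (5, 7, 25, 33))
        mean, n = plot_mean_vi(_index_map(values, valid), _green(green), roi)
        acc, cnt = 0.0, 0
        for r in range(5, 25):
            for c in range(7, 33):
                if green[r, c] and valid[r, c]:
                    acc += values[r, c]
                    cnt += 1
        assert n == cnt
        assert mean == pytest.approx(acc / cnt, abs=1e-12)

    def test_zero_usable_pixels_signalled(self):
        mean, n = plot_mean_vi(
            _index_map(np.ones((4, 4))), _green(np.zeros((4, 4))), PlotRoi("p", (0, 0, 4, 4))
        )
        assert n == 0 and np.isnan(mean)


class TestLinearR2:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        assert linear_r2(x, 2 * x + 1) == pytest.approx(1.0)

    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        assert linear_r2(x, y) < 0.01

    def test_matches_closed_form_pearson(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        num = np.sum((x - x.mean()) * (y - y.mean())) ** 2
        den = np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        assert linear_r2(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_r2([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=30),
        st.floats(0.1, 10),
        st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_affine_invariant(self, xs, a, b):
        rng = np.random.default_rng(0)
        x = np.asarray(xs)
        if np.ptp(x) < 1e-6:
            return
        y = x + rng.normal(size=x.size)
        if np.ptp(y) < 1e-6:
            return
        r2 = linear_r2(x, y)
        assert linear_r2(y, x) == pytest.approx(r2, abs=1e-9)
        assert linear_r2(a * x + b, y) == pytest.approx(r2, abs=1e-6)


class TestMetrics:
    def test_identity_gives_zeros(self):
        res = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.rmse, res.mae, res.ae) == (0.0, 0.0, 0.0)

    def test_two_point_hand_example(self):
        res = metrics([2.0, 2.0], [1.0, 4.0])
        assert res.rmse == pytest.approx(np.sqrt(2.5), abs=1e-9)
        assert res.mae == pytest.approx(1.5, abs=1e-9)
        assert res.ae == pytest.approx(1.0 / 1.0 + 2.0 / 4.0, abs=1e-9)

    def test_single_pair(self):
        res = metrics([3.0], [2.0])
        assert (res.rmse, res.mae, res.ae) == (1.0, 1.0, 0.5)

    def test_zero_truth_with_ae_rejected(self):
        with pytest.raises(ZeroDivisionError):
            metrics([1.0], [0.0])
        assert metrics([1.0], [0.0], with_ae=False).ae is None

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_rmse_at_least_mae(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 50)
        P, M = rng.normal(size=n), rng.normal(size=n) + 5.0
        res = metrics(P, M, with_ae=False)
        assert res.rmse >= res.mae - 1e-12


class TestNormalizeSeries:
    def test_linear_case(self):
        np.testing.assert_allclose(normalize_series([10, 20, 30]), [0, 0.5, 1])

    def test_idempotent_on_full_unit_range(self):
        v = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(normalize_series(v), v)

    def test_affine_invariance(self):
        v = np.array([3.0, 7.0, 5.0, 11.0])
        np.testing.assert_allclose(normalize_series(v), normalize_series(4 * v - 2))

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_series([2.0, 2.0, 2.0])


class TestStageScreen:
    @staticmethod
    def _obs(n_plots=6, n_dates=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for d in range(n_dates):
            for p in range(n_plots):
                rows.append(
                    {
                        "plot_id": f"p{p:02d}",
                        "date": f"d{d}",
                        "E8_MRBVI": rng.normal(),
                        "spad": rng.normal(40, 5),
                        "n_green": 100,
                    }
                )
        return pd.DataFrame(rows)

    def test_self_regression_gives_unit_r2(self):
        obs = self._obs()
        obs["spad"] = obs["E8_MRBVI"] * 3 + 1  # response equals the index
        screen = stage_screen(obs, {f"p{p:02d}": 1.0 + p for p in range(6)},
                              indices=[IndexId.E8_MRBVI])
        assert np.allclose(screen.per_date["r2_spad"], 1.0)

    def test_permuted_yields_give_near_zero_average(self):
        rng = np.random.default_rng(42)
        obs = self._obs(n_plots=40, n_dates=6, seed=1)
        yields = {f"p{p:02d}": float(v) for p, v in enumerate(rng.permutation(40))}
        screen = stage_screen(obs, yields, indices=[IndexId.E8_MRBVI])
        assert screen.mean_r2("E8_MRBVI", "yield") < 0.15

    def test_sparse_dates_reported_missing_not_raised(self):
        obs = self._obs(n_plots=4, n_dates=2)
        obs.loc[obs["date"] == "d0", "E8_MRBVI"] = np.nan
        obs.loc[obs["date"].eq("d0") & obs["plot_id"].isin(["p00", "p01"]), "E8_MRBVI"] = 1.0
        screen = stage_screen(obs, {f"p{p:02d}": float(p) for p in range(4)},
                              indices=[IndexId.E8_MRBVI])
        d0 = screen.per_date[screen.per_date["date"] == "d0"]
        assert np.isnan(d0["r2_spad"].iloc[0])
        assert d0["n_plots"].iloc[0] == 2

    def test_late_season_r2_exceeds_early_for_every_index(
        self, default_season, default_observations
    ):
        screen = stage_screen(default_observations, default_season.yield_table)
        per_date = screen.per_date
        dates = sorted(per_date["date"].unique())
        early = per_date[per_date["date"].isin(dates[:3])].groupby("index").mean(numeric_only=True)
        late = per_date[per_date["date"].isin(dates[-8:])].groupby("index").mean(numeric_only=True)
        assert (late["r2_spad"] > early["r2_spad"]).all()
        assert (late["r2_yield"] > early["r2_yield"]).all()


class TestTrajectoryCompare:
    def test_identical_series_zero_error(self):
        s = pd.Series([1.0, 3.0, 2.0, 5.0])
        vi = pd.DataFrame({"E8_MRBVI": s})
        out = trajectory_compare(vi, s)
        assert out.loc["E8_MRBVI", "mae"] == 0.0
        assert out.loc["E8_MRBVI", "ae"] == 0.0

    def test_constant_offset_removed_by_normalization(self):
        s = pd.Series([1.0, 3.0, 2.0, 5.0])
        vi = pd.DataFrame({"E8_MRBVI": s + 100.0})
        out = trajectory_compare(vi, s)
        assert out.loc["E8_MRBVI", "mae"] == pytest.approx(0.0, abs=1e-12)

    def test_anti_correlated_series_compared_in_flipped_orientation(self):
        s = pd.Series([1.0, 3.0, 2.0, 5.0])
        vi = pd.DataFrame({"E8_MRBVI": -s})
        out = trajectory_compare(vi, s)
        assert bool(out.loc["E8_MRBVI", "inverted"])
        assert out.loc["E8_MRBVI", "mae"] == pytest.approx(0.0, abs=1e-12)

    def test_mrbvi_tracks_spad_on_synthetic_season(
        self, default_observations
    ):
        vi, spad = trajectory_from_observations(default_observations)
        out = trajectory_compare(vi, spad)
        assert out.loc["E8_MRBVI", "mae"] < 0.05
        assert out["rank"].min() == 1
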