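"""Plot-level statistics linking vegetation indices to chlorophyll and yield.

The workflow mirrors a standard small-plot UAV analysis: per plot and date,
the mean of each vegetation index over the green canopy pixels inside the
plot ROI is computed (zonal statistics restricted to the ExG−ExR mask);
per date, a simple linear regression of those means against plot-mean SPAD
chlorophyll readings (and against harvest yields) yields an R² screen over
the season; and per index, the date-series of spatially averaged values is
min–max normalized and compared with the normalized SPAD trajectory via
mean absolute error and summed relative error.

Error metrics follow the conventional definitions

    RMSE = sqrt(mean((P − M)²))
    MAE  = mean(|P − M|)
    AE   = Σ |Pᵢ − Mᵢ| / Mᵢ        (sum of per-sample relative errors)

with the per-sample mean of the relative errors (AE / n) also reported,
since the summed form grows with series length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .indices import ALL_INDICES, DEFAULT_COM1_K, IndexId, IndexMap, compute_index, normalize_bands
from .raster import PlotRoi, RgbRaster
from .segmentation import GreenMask, green_mask

__all__ = [
    "EvalResult",
    "plot_mean_vi",
    "linear_r2",
    "metrics",
    "normalize_series",
    "compute_observations",
    "stage_screen",
    "StageScreen",
    "trajectory_from_observations",
    "trajectory_compare",
]


@dataclass(frozen=True)
class EvalResult:
    """Prediction-vs-truth error summary."""

    rmse: float
    mae: float
    ae: float | None = None  # sum of relative errors; None if not computable
    r2: float | None = None

    @property
    def mean_relative_error(self) -> float | None:
        return None if self.ae is None else self.ae / self._n if self._n else None

    # n is carried only to derive the mean relative error
    _n: int = 0


def plot_mean_vi(
    index_map: IndexMap, mask: GreenMask, roi: PlotRoi
) -> tuple[float, int]:
    """Mean index value over green, valid pixels inside a plot ROI.

    Returns ``(mean, n_pixels_used)``; the mean is NaN when no pixel inside
    the ROI is both green and valid, signalling an undefined observation
    that the caller should drop.
    """
    r0, c0, r1, c1 = roi.rect
    h, w = index_map.values.shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"ROI {roi.plot_id!r} rect {roi.rect} outside map {(h, w)}")
    sel = (
        mask.mask[r0:r1, c0:c1]
        & index_map.valid_mask[r0:r1, c0:c1]
    )
    n = int(sel.sum())
    if n == 0:
        return math.nan, 0
    return float(index_map.values[r0:r1, c0:c1][sel].mean()), n


def linear_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """R² of the ordinary least-squares simple linear fit of y on x.

    Equals the squared Pearson correlation.  Requires at least 3 points and
    non-constant x.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression is degenerate")
    return float(stats.linregress(x, y).rvalue ** 2)


def metrics(
    predictions: Sequence[float],
    truths: Sequence[float],
    with_ae: bool = True,
) -> EvalResult:
    """RMSE, MAE and (optionally) summed relative error of predictions.

    ``with_ae=True`` with any zero truth raises ``ZeroDivisionError``; pass
    ``with_ae=False`` when relative errors are meaningless for the data.
    """
    P = np.asarray(predictions, dtype=np.float64)
    M = np.asarray(truths, dtype=np.float64)
    if P.shape != M.shape or P.size < 1:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    resid = P - M
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ae = None
    if with_ae:
        if np.any(M == 0):
            raise ZeroDivisionError("relative error undefined: some truth is 0")
        ae = float(np.sum(np.abs(resid) / np.abs(M)))
    r2 = None
    if P.size >= 3 and np.ptp(M) > 0:
        r2 = linear_r2(M, P)
    return EvalResult(rmse=rmse, mae=mae, ae=ae, r2=r2, _n=P.size)


def normalize_series(values: Sequence[float]) -> np.ndarray:
    """Min–max normalize a series to [0, 1]; constant series are degenerate."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 values to normalize")
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        raise ValueError("constant series cannot be min-max normalized")
    return (v - lo) / (hi - lo)


def compute_observations(
    mosaics: Sequence[RgbRaster],
    rois: Sequence[PlotRoi],
    spad_table: pd.DataFrame | None = None,
    indices: Iterable[IndexId] = ALL_INDICES,
    threshold: float = 0.0,
    k: float = DEFAULT_COM1_K,
) -> pd.DataFrame:
    """Build the per-(plot, date) observation table for a whole season.

    For each date the mosaic is normalized once, segmented once, and every
    index map computed once; plot means are then zonal reductions over each
    ROI.  The result has one row per (plot, date) with columns ``plot_id``,
    ``date``, ``n_green``, one column per index id, and ``spad`` merged in
    from ``spad_table`` (columns plot_id, date, spad) when provided.
    Index means are NaN where a plot has no green pixels at a date.
    """
    indices = [IndexId(i) for i in indices]
    rows = []
    for mosaic in mosaics:
        chrom = normalize_bands(mosaic)
        gmask = green_mask(chrom, threshold=threshold)
        maps = {idx: compute_index(chrom, idx, k=k) for idx in indices}
        for roi in rois:
            rec: dict = {"plot_id": roi.plot_id, "date": mosaic.date_label}
            n_used = 0
            for idx, imap in maps.items():
                mean, n = plot_mean_vi(imap, gmask, roi)
                rec[idx.value] = mean
                n_used = max(n_used, n)
            rec["n_green"] = n_used
            rows.append(rec)
    obs = pd.DataFrame(rows)
    if spad_table is not None:
        obs = obs.merge(spad_table, on=["plot_id", "date"], how="left")
    return obs.sort_values(["date", "plot_id"]).reset_index(drop=True)


@dataclass
class StageScreen:
    """Per-date R² screen of every index against chlorophyll and yield."""

    per_date: pd.DataFrame  # columns: date, index, r2_spad, r2_yield, n_plots
    per_index: pd.DataFrame  # index: IndexId value; columns: r2_spad, r2_yield

    def mean_r2(self, index: IndexId | str, response: str = "spad") -> float:
        return float(self.per_index.loc[IndexId(index).value, f"r2_{response}"])


def _safe_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.ptp(x[ok]) == 0:
        return math.nan
    return linear_r2(x[ok], y[ok])


def stage_screen(
    observations: pd.DataFrame,
    yields: Mapping[str, float] | pd.DataFrame,
    indices: Iterable[IndexId] = ALL_INDICES,
) -> StageScreen:
    """Regress per-plot index means on SPAD and on yield, date by date.

    Dates where fewer than 3 plots have a defined index mean are reported
    with NaN R² rather than raised, since an open early-season canopy can
    legitimately produce empty plots.  Per-index averages are taken over the
    dates where the regression was defined.
    """
    if isinstance(yields, pd.DataFrame):
        yields = dict(zip(yields["plot_id"], yields["yield"]))
    indices = [IndexId(i) for i in indices]
    records = []
    for date, grp in observations.groupby("date", sort=True):
        y_yield = grp["plot_id"].map(yields).to_numpy(dtype=np.float64)
        y_spad = grp["spad"].to_numpy(dtype=np.float64) if "spad" in grp else None
        for idx in indices:
            x = grp[idx.value].to_numpy(dtype=np.float64)
            records.append(
                {
                    "date": date,
                    "index": idx.value,
                    "r2_spad": _safe_r2(x, y_spad) if y_spad is not None else math.nan,
                    "r2_yield": _safe_r2(x, y_yield),
                    "n_plots": int(np.isfinite(x).sum()),
                }
            )
    per_date = pd.DataFrame(records)
    per_index = per_date.groupby("index")[["r2_spad", "r2_yield"]].mean()
    per_index = per_index.reindex([i.value for i in indices])
    return StageScreen(per_date=per_date, per_index=per_index)


def trajectory_from_observations(
    observations: pd.DataFrame, indices: Iterable[IndexId] = ALL_INDICES
) -> tuple[pd.DataFrame, pd.Series]:
    """Spatially averaged per-date series of each index and of SPAD.

    Plot/date cells with no green pixels (NaN means) are skipped by the
    spatial average.
    """
    indices = [IndexId(i).value for i in indices]
    by_date = observations.groupby("date", sort=True)
    vi_series = by_date[indices].mean()
    spad_series = by_date["spad"].mean()
    return vi_series, spad_series


def trajectory_compare(
    vi_series: pd.DataFrame, spad_series: pd.Series
) -> pd.DataFrame:
    """Compare each index's normalized seasonal trajectory with SPAD's.

    Both series are min–max normalized over the dates, then MAE and summed
    relative error (AE) are computed between them.  An index whose seasonal
    course is anti-correlated with SPAD (several of the red-driven indices
    fall as chlorophyll rises) is compared in flipped orientation
    (``1 − normalized``), since it carries the same trajectory information
    with opposite sign; the ``inverted`` column records the flip.  The date
    at which the normalized SPAD value is exactly 0 contributes no AE term
    (its relative error is undefined).  Returns a DataFrame indexed by
    index id with columns ``mae``, ``ae``, ``mean_re``, ``inverted`` and
    ``rank`` (1 = smallest MAE).
    """
    if len(vi_series) != len(spad_series):
        raise ValueError("vi_series and spad_series must cover the same dates")
    spad = spad_series.to_numpy(dtype=np.float64)
    m = normalize_series(spad)
    nonzero = m > 0
    out = {}
    for col in vi_series.columns:
        v = vi_series[col].to_numpy(dtype=np.float64)
        p = normalize_series(v)
        inverted = bool(np.corrcoef(v, spad)[0, 1] < 0)
        if inverted:
            p = 1.0 - p
        mae = float(np.mean(np.abs(p - m)))
        ae = float(np.sum(np.abs(p[nonzero] - m[nonzero]) / m[nonzero]))
        out[col] = {
            "mae": mae,
            "ae": ae,
            "mean_re": ae / int(nonzero.sum()),
            "inverted": inverted,
        }
    table = pd.DataFrame(out).T
    table = table.astype({"mae": float, "ae": float, "mean_re": float, "inverted": bool})
    table["rank"] = table["mae"].rank(method="min").astype(int)
    return table
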