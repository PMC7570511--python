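"""Synthetic multi-date season generator.

Emulates a small-plot field trial observed by a UAV RGB camera: a grid of
fertilizer plots photographed on ``n_dates`` acquisition dates across a
growing season.  Each plot's canopy closure follows a logistic curve in
date index; its leaf chlorophyll follows the same logistic scaled by
per-plot base and amplitude parameters; leaf color is a deterministic
function of chlorophyll (greener and bluer at high chlorophyll, yellower
and redder at low); the background is soil-colored; and the harvest yield
(grams per hundred grains) is an affine function of mean late-season
chlorophyll plus noise.

The leaf color model is parameterised directly by the red/blue contrast:
the ratio R/B is solved so that the canopy's MRBVI value is an affine,
strictly decreasing function of chlorophyll between two anchor values.
This builds in, by construction, the physical premise that the red band is
the most chlorophyll-sensitive of the three — the property the index-based
chlorophyll regressions downstream are meant to detect.

Chromaticities are converted back to 8-bit digital numbers by scaling with
a random per-pixel brightness and rounding, so the downstream brightness
normalisation is genuinely exercised.  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .raster import PlotRoi, RgbRaster, write_raster, write_rois

__all__ = [
    "LeafColorModel",
    "SeasonConfig",
    "SyntheticSeason",
    "ConfigError",
    "generate_season",
    "green_fraction_truth",
    "write_season",
    "DEFAULT_DATE_LABELS",
]

#: Eleven ISO acquisition dates spanning early July to the end of September,
#: matching the cadence of a weekly-to-biweekly flight campaign over maize.
DEFAULT_DATE_LABELS: tuple[str, ...] = (
    "2019-07-07",
    "2019-07-14",
    "2019-07-22",
    "2019-07-28",
    "2019-08-04",
    "2019-08-11",
    "2019-08-18",
    "2019-08-25",
    "2019-09-07",
    "2019-09-16",
    "2019-09-30",
)

#: Treatment labels for a 20-plot factorial fertilizer trial (nitrogen N,
#: phosphate P, potassium K, straw S, organic O), used purely as plot labels.
DEFAULT_TREATMENTS: tuple[str, ...] = (
    "N1P1K2", "N3P1K1", "N3P3K1", "N2S1",
    "N1P1K1", "N3P3K2", "N3P2K1", "N2O1",
    "N1P2K1", "N2P2K2", "N4P3K1", "N3S1",
    "N1P3K1", "N2P1K1", "N4P2K1", "N3O1",
    "N2P3K1", "N2P2K1", "N4P1K1", "N4P2K2",
)


class ConfigError(ValueError):
    """Invalid season configuration; the message names the offending field."""


@dataclass(frozen=True)
class LeafColorModel:
    """Maps leaf chlorophyll (SPAD-like units) to a chromaticity triplet.

    Between ``chl_lo`` and ``chl_hi`` the canopy MRBVI value moves linearly
    from ``mrbvi_lo`` down to ``mrbvi_hi`` (strictly decreasing: more
    chlorophyll means less red relative to blue) and the green share moves
    linearly from ``green_lo`` up to ``green_hi``.  Outside the anchor range
    the mapping saturates.  The returned triplets always lie on the simplex.
    """

    chl_lo: float = 20.0
    chl_hi: float = 55.0
    mrbvi_lo: float = 0.90
    mrbvi_hi: float = -0.70
    green_lo: float = 0.43
    green_hi: float = 0.46

    def chromaticity(self, chl) -> np.ndarray:
        """Return ``(..., 3)`` simplex chromaticities for chlorophyll values."""
        chl = np.asarray(chl, dtype=np.float64)
        u = np.clip((chl - self.chl_lo) / (self.chl_hi - self.chl_lo), 0.0, 1.0)
        m = self.mrbvi_lo + (self.mrbvi_hi - self.mrbvi_lo) * u
        # green share saturates at both ends of the chlorophyll range
        # (smoothstep), as pigment-driven greenness does in real leaves
        g = self.green_lo + (self.green_hi - self.green_lo) * u * u * (3.0 - 2.0 * u)
        # R/B ratio realising MRBVI = m:  m = (rho^2 - 1) / (rho^2 + 1)
        rho = np.sqrt((1.0 + m) / (1.0 - m))
        r = (1.0 - g) * rho / (1.0 + rho)
        b = (1.0 - g) / (1.0 + rho)
        return np.stack([r, g, b], axis=-1)


@dataclass(frozen=True)
class SeasonConfig:
    """Parameters of one synthetic season.

    Chlorophyll trajectories are ``base_i + amp_i * logistic(t)`` with the
    per-plot ``base_i`` and ``amp_i`` drawn uniformly from
    ``chl_base ± chl_base_spread/2`` and ``chl_amplitude ±
    chl_amplitude_spread/2``.  Yield is ``yield_intercept + yield_slope ×
    (mean chlorophyll over the last n_yield_dates dates) + N(0,
    yield_noise_sd)``.
    """

    n_dates: int = 11
    n_plots: int = 20
    plot_px: tuple[int, int] = (80, 100)  # (width, height) of one plot
    gutter_px: int = 10
    grid_cols: int = 4
    canopy_midpoint: float = 2.5  # date index of logistic inflection
    canopy_rate: float = 1.2  # logistic steepness per date step
    chl_base: float = 26.0
    chl_base_spread: float = 4.0
    chl_amplitude: float = 21.0
    chl_amplitude_spread: float = 14.0
    leaf_color: LeafColorModel = field(default_factory=LeafColorModel)
    soil_chroma: tuple[float, float, float] = (0.40, 0.34, 0.26)
    chroma_jitter_sd: float = 0.01
    spad_noise_sd: float = 1.0
    brightness_range: tuple[float, float] = (120.0, 240.0)
    yield_intercept: float = 5.0
    yield_slope: float = 0.55
    yield_noise_sd: float = 0.8
    n_yield_dates: int = 3
    date_labels: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_dates < 2:
            raise ConfigError("n_dates must be >= 2")
        if self.n_plots < 2:
            raise ConfigError("n_plots must be >= 2")
        if min(self.plot_px) < 1:
            raise ConfigError("plot_px dimensions must be positive")
        if self.gutter_px < 0:
            raise ConfigError("gutter_px must be non-negative")
        if self.grid_cols < 1:
            raise ConfigError("grid_cols must be positive")
        if self.yield_noise_sd < 0:
            raise ConfigError("yield_noise_sd must be >= 0")
        if self.spad_noise_sd < 0:
            raise ConfigError("spad_noise_sd must be >= 0")
        if self.chroma_jitter_sd < 0:
            raise ConfigError("chroma_jitter_sd must be >= 0")
        if not (0 < self.brightness_range[0] <= self.brightness_range[1] <= 255):
            raise ConfigError("brightness_range must satisfy 0 < lo <= hi <= 255")
        sc = np.asarray(self.soil_chroma)
        if sc.min() < 0 or not np.isclose(sc.sum(), 1.0):
            raise ConfigError("soil_chroma must lie on the simplex")
        if not 1 <= self.n_yield_dates <= self.n_dates:
            raise ConfigError("n_yield_dates must be in [1, n_dates]")
        if self.date_labels is not None and len(self.date_labels) != self.n_dates:
            raise ConfigError("date_labels length must equal n_dates")

    def resolved_date_labels(self) -> tuple[str, ...]:
        if self.date_labels is not None:
            return tuple(self.date_labels)
        if self.n_dates == len(DEFAULT_DATE_LABELS):
            return DEFAULT_DATE_LABELS
        return tuple(f"date-{i:02d}" for i in range(self.n_dates))

    def canopy_fraction(self, t) -> np.ndarray:
        """Logistic canopy-closure fraction at date index ``t``."""
        t = np.asarray(t, dtype=np.float64)
        return 1.0 / (1.0 + np.exp(-self.canopy_rate * (t - self.canopy_midpoint)))


@dataclass
class SyntheticSeason:
    """One generated season: imagery, ROIs, reference tables, and the truth."""

    mosaics: list[RgbRaster]
    rois: list[PlotRoi]
    spad_table: pd.DataFrame  # columns: plot_id, date, spad
    yield_table: pd.DataFrame  # columns: plot_id, yield
    truth: dict

    @property
    def date_labels(self) -> list[str]:
        return [m.date_label for m in self.mosaics]

    @property
    def plot_ids(self) -> list[str]:
        return [r.plot_id for r in self.rois]


def _layout_rois(config: SeasonConfig) -> tuple[list[PlotRoi], tuple[int, int]]:
    """Grid layout of plot rectangles plus the enclosing mosaic shape."""
    w, h = config.plot_px
    g = config.gutter_px
    cols = config.grid_cols
    rows = -(-config.n_plots // cols)
    rois = []
    for i in range(config.n_plots):
        rr, cc = divmod(i, cols)
        r0 = g + rr * (h + g)
        c0 = g + cc * (w + g)
        treatment = DEFAULT_TREATMENTS[i] if i < len(DEFAULT_TREATMENTS) else None
        rois.append(
            PlotRoi(
                plot_id=f"plot{i + 1:02d}",
                rect=(r0, c0, r0 + h, c0 + w),
                treatment=treatment,
            )
        )
    shape = (g + rows * (h + g), g + cols * (w + g))
    return rois, shape


def _paint(
    rng: np.random.Generator,
    chroma: np.ndarray,
    n: int,
    jitter_sd: float,
    brightness_range: tuple[float, float],
) -> np.ndarray:
    """Render ``n`` pixels of a nominal chromaticity as 8-bit digital numbers."""
    c = np.broadcast_to(chroma, (n, 3)).copy()
    if jitter_sd > 0:
        c += rng.normal(0.0, jitter_sd, size=(n, 3))
        c = np.clip(c, 1e-6, None)
        c /= c.sum(axis=1, keepdims=True)
    brightness = rng.uniform(*brightness_range, size=(n, 1))
    dn = np.rint(c * brightness)
    return np.clip(dn, 0, 255).astype(np.uint8)


def generate_season(config: SeasonConfig) -> SyntheticSeason:
    """Generate a full synthetic season, deterministic for a fixed seed.

    Canopy pixels are a uniformly random subset of each plot of exact size
    ``round(f(t) · n_pixels)``, so the painted canopy fraction matches the
    logistic curve to within half a pixel — the truth oracle returned by
    :func:`green_fraction_truth` is the painted fraction itself.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = config.resolved_date_labels()
    rois, (H, W) = _layout_rois(config)

    # per-plot chlorophyll trajectory parameters
    base = config.chl_base + config.chl_base_spread * (
        rng.uniform(size=config.n_plots) - 0.5
    )
    amp = config.chl_amplitude + config.chl_amplitude_spread * (
        rng.uniform(size=config.n_plots) - 0.5
    )
    growth = config.canopy_fraction(np.arange(config.n_dates))
    chl = base[:, None] + amp[:, None] * growth[None, :]  # (plots, dates)

    canopy_frac = np.empty((config.n_plots, config.n_dates))
    mosaics: list[RgbRaster] = []
    for t, label in enumerate(labels):
        frame = np.empty((H, W, 3), dtype=np.uint8)
        frame.reshape(-1, 3)[:] = _paint(
            rng,
            np.asarray(config.soil_chroma),
            H * W,
            config.chroma_jitter_sd,
            config.brightness_range,
        )
        f_t = float(growth[t])
        for i, roi in enumerate(rois):
            r0, c0, r1, c1 = roi.rect
            n = roi.n_pixels
            n_canopy = int(round(f_t * n))
            canopy_frac[i, t] = n_canopy / n
            if n_canopy == 0:
                continue
            flat_idx = rng.permutation(n)[:n_canopy]
            leaf_chroma = config.leaf_color.chromaticity(chl[i, t])
            leaf_dn = _paint(
                rng,
                leaf_chroma,
                n_canopy,
                config.chroma_jitter_sd,
                config.brightness_range,
            )
            block = frame[r0:r1, c0:c1].reshape(-1, 3)
            block[flat_idx] = leaf_dn
            frame[r0:r1, c0:c1] = block.reshape(r1 - r0, c1 - c0, 3)
        mosaics.append(RgbRaster(frame, date_label=label))

    spad = chl + rng.normal(0.0, config.spad_noise_sd, size=chl.shape)
    spad_table = pd.DataFrame(
        {
            "plot_id": np.repeat([r.plot_id for r in rois], config.n_dates),
            "date": list(labels) * config.n_plots,
            "spad": spad.ravel(),
        }
    )

    late_chl = chl[:, -config.n_yield_dates :].mean(axis=1)
    yields = (
        config.yield_intercept
        + config.yield_slope * late_chl
        + rng.normal(0.0, config.yield_noise_sd, size=config.n_plots)
    )
    yield_table = pd.DataFrame(
        {"plot_id": [r.plot_id for r in rois], "yield": yields}
    )

    truth = {
        "config": config,
        "chl": chl,
        "chl_base": base,
        "chl_amplitude": amp,
        "late_chl": late_chl,
        "canopy_fraction": canopy_frac,
        "date_labels": list(labels),
    }
    return SyntheticSeason(
        mosaics=mosaics,
        rois=rois,
        spad_table=spad_table,
        yield_table=yield_table,
        truth=truth,
    )


def green_fraction_truth(
    season: SyntheticSeason, plot_id: str, date: int | str
) -> float:
    """Exact canopy fraction painted into one plot at one date."""
    try:
        i = season.plot_ids.index(plot_id)
    except ValueError:
        raise KeyError(f"unknown plot_id {plot_id!r}") from None
    if isinstance(date, str):
        try:
            t = season.date_labels.index(date)
        except ValueError:
            raise KeyError(f"unknown date label {date!r}") from None
    else:
        t = int(date)
        if not 0 <= t < len(season.mosaics):
            raise KeyError(f"date index {t} out of range")
    return float(season.truth["canopy_fraction"][i, t])


def write_season(season: SyntheticSeason, outdir: str | Path) -> Path:
    """Write mosaics (TIFF), ROIs (JSON) and reference tables (CSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for mosaic in season.mosaics:
        write_raster(mosaic, outdir / f"mosaic_{mosaic.date_label}.tif")
    write_rois(season.rois, outdir / "rois.json")
    season.spad_table.to_csv(outdir / "spad.csv", index=False)
    season.yield_table.to_csv(outdir / "yields.csv", index=False)
    return outdir
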