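"""Pixel-wise scale-up: apply a plot-trained yield model to whole mosaics.

The plot-level model sees one feature vector per plot (index × date means
over green pixels).  Scale-up builds the same feature vector at every pixel
of the co-registered multi-date mosaics and runs the model over them,
producing a wall-to-wall predicted-yield raster.  Before mapping, the model
is refit on all plots (no fold held out), since the map is an application of
the final model rather than a validation exercise.

Pixels invalid in any constituent (index, date) layer are no-data.  By
default pixels not classified as green canopy on the final window date are
also masked: the model was trained on green-pixel statistics, so applying it
to bare soil is out-of-distribution.  Mapping all pixels is available via
``mask_non_green=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

from .indices import ALL_INDICES, DEFAULT_COM1_K, IndexId, compute_index, normalize_bands
from .raster import PlotRoi, RgbRaster
from .segmentation import green_mask
from .yield_ml import FeatureMatrix, FoldPreprocessor, LooResult, YieldModelSpec, make_model

__all__ = [
    "IndexStack",
    "FittedYieldModel",
    "build_stack",
    "fit_full_model",
    "predict_map",
    "plot_map_means",
    "write_yield_map",
]


@dataclass
class IndexStack:
    """Per-pixel feature cube ordered exactly like a training FeatureMatrix."""

    features: np.ndarray  # (H, W, n_features) float32
    valid_mask: np.ndarray  # (H, W) bool: valid in every layer
    column_labels: list[tuple[str, str]]  # (index id, date label), index-major
    geotransform: tuple[float, ...] | None = None


@dataclass
class FittedYieldModel:
    """A model refit on all plots, plus its preprocessing and feature layout."""

    model: object
    preprocessor: FoldPreprocessor
    column_labels: list[tuple[str, str]]
    spec: YieldModelSpec


def build_stack(
    mosaics: Sequence[RgbRaster],
    window: Sequence[str],
    indices: Iterable[IndexId] = ALL_INDICES,
    k: float = DEFAULT_COM1_K,
    mask_non_green: bool = True,
    threshold: float = 0.0,
) -> IndexStack:
    """Compute every (index, date) layer of the prediction window per pixel.

    All mosaics must share one shape (co-registered).  Column order is
    index-major, date-minor with dates sorted, matching
    :func:`mrbvi.yield_ml.build_features`.
    """
    indices = [IndexId(i) for i in indices]
    window = sorted(window)
    by_date = {m.date_label: m for m in mosaics}
    missing = [d for d in window if d not in by_date]
    if missing:
        raise ValueError(f"window dates with no mosaic: {missing}")
    shapes = {by_date[d].shape for d in window}
    if len(shapes) > 1:
        raise ValueError(f"mosaics are not co-registered; shapes {sorted(shapes)}")
    (H, W) = shapes.pop()

    layers: dict[tuple[str, str], np.ndarray] = {}
    valid = np.ones((H, W), dtype=bool)
    for d in window:
        chrom = normalize_bands(by_date[d])
        valid &= chrom.valid_mask
        for idx in indices:
            imap = compute_index(chrom, idx, k=k)
            layers[(idx.value, d)] = imap.values.astype(np.float32)
            valid &= imap.valid_mask
        if d == window[-1] and mask_non_green:
            valid &= green_mask(chrom, threshold=threshold).mask

    column_labels = [(i.value, d) for i in indices for d in window]
    features = np.stack([layers[lab] for lab in column_labels], axis=-1)
    geot = by_date[window[0]].geotransform
    return IndexStack(
        features=features,
        valid_mask=valid,
        column_labels=column_labels,
        geotransform=geot,
    )


def fit_full_model(features: FeatureMatrix, spec: YieldModelSpec) -> FittedYieldModel:
    """Refit a model spec on every plot (the pre-mapping training step)."""
    prep = FoldPreprocessor(spec.standardize_resolved).fit(features.X)
    model = make_model(spec).fit(prep.transform(features.X), features.y)
    return FittedYieldModel(
        model=model,
        preprocessor=prep,
        column_labels=list(features.column_labels),
        spec=spec,
    )


def predict_map(
    stack: IndexStack, fitted: FittedYieldModel, chunk: int = 200_000
) -> np.ndarray:
    """Predict yield at every valid pixel; no-data pixels are NaN.

    Raises if the stack's feature columns do not match the model's training
    columns exactly (same indices, same dates, same order).
    """
    if stack.column_labels != fitted.column_labels:
        diff = [
            (a, b)
            for a, b in zip(stack.column_labels, fitted.column_labels)
            if a != b
        ]
        raise ValueError(
            "feature columns of the stack and the trained model differ: "
            f"{diff or 'length mismatch'}"
        )
    H, W, F = stack.features.shape
    out = np.full(H * W, np.nan, dtype=np.float32)
    flat = stack.features.reshape(-1, F)
    idx = np.flatnonzero(stack.valid_mask.ravel())
    for start in range(0, idx.size, chunk):
        sel = idx[start : start + chunk]
        X = fitted.preprocessor.transform(flat[sel].astype(np.float64))
        out[sel] = fitted.model.predict(X)
    return out.reshape(H, W)


def plot_map_means(yield_map: np.ndarray, rois: Sequence[PlotRoi]) -> dict[str, float]:
    """Mean predicted yield over each plot ROI (NaN if a plot is all no-data)."""
    means = {}
    for roi in rois:
        r0, c0, r1, c1 = roi.rect
        block = yield_map[r0:r1, c0:c1]
        finite = np.isfinite(block)
        means[roi.plot_id] = float(block[finite].mean()) if finite.any() else float("nan")
    return means


def write_yield_map(yield_map: np.ndarray, path: str | Path) -> Path:
    """Write the predicted-yield raster as single-band float32 TIFF (NaN nodata)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(yield_map, dtype=np.float32))
    return path
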