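"""Raster and ROI handling for multi-date RGB plot imagery.

A mosaic is represented as an :class:`RgbRaster` — a ``(height, width, 3)``
array of digital numbers in band order (r, g, b) with an optional affine
geotransform.  Plot regions are axis-aligned pixel rectangles
(:class:`PlotRoi`) in 0-based, half-open ``(row0, col0, row1, col1)``
convention.  TIFF files are read and written with :mod:`tifffile`; PNG with
Pillow.  Because this stack has no GDAL bindings, a geotransform is
round-tripped through a small JSON sidecar (``<raster>.aux.json``) rather
than embedded GeoTIFF tags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "RgbRaster",
    "PlotRoi",
    "read_raster",
    "write_raster",
    "read_rois",
    "write_rois",
    "extract_subsamples",
]


@dataclass
class RgbRaster:
    """A 3-band digital-number image, one per acquisition date.

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` array of non-negative digital numbers,
        band-ordered (r, g, b).  Integer or float dtype.
    geotransform
        Optional 6-tuple affine mapping pixel to world coordinates,
        ``(x0, dx, rx, y0, ry, dy)`` in the GDAL convention.
    date_label
        Acquisition date as an opaque, lexicographically orderable string
        (ISO dates recommended).
    """

    pixels: np.ndarray
    geotransform: tuple[float, ...] | None = None
    date_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"raster must be (height, width, 3); got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("raster must have positive height and width")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[:2]

    def crop(self, rect: tuple[int, int, int, int]) -> "RgbRaster":
        """Return the sub-raster for a half-open ``(r0, c0, r1, c1)`` rectangle."""
        r0, c0, r1, c1 = rect
        h, w = self.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"rectangle {rect} not within raster of shape {(h, w)}")
        return RgbRaster(
            self.pixels[r0:r1, c0:c1].copy(),
            geotransform=self.geotransform,
            date_label=self.date_label,
        )


@dataclass(frozen=True)
class PlotRoi:
    """A named plot region: half-open pixel rectangle plus treatment label."""

    plot_id: str
    rect: tuple[int, int, int, int]
    treatment: str | None = None

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.rect
        if not (r0 < r1 and c0 < c1):
            raise ValueError(
                f"ROI {self.plot_id!r}: rectangle {self.rect} must satisfy "
                "row0 < row1 and col0 < col1"
            )

    @property
    def height(self) -> int:
        return self.rect[2] - self.rect[0]

    @property
    def width(self) -> int:
        return self.rect[3] - self.rect[1]

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".aux.json")


def read_raster(path: str | Path, date_label: str = "") -> RgbRaster:
    """Read a 3-band TIFF or PNG into an :class:`RgbRaster`.

    Digital numbers are preserved exactly.  Raises ``IOError`` for a missing
    file and ``ValueError`` if the image does not have exactly 3 bands.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = np.asarray(Image.open(path))
    else:
        raise IOError(f"unsupported raster format {suffix!r}: {path}")
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 3 and arr.shape[2] != 3:
        arr = np.moveaxis(arr, 0, 2)  # band-first TIFF layout
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"{path}: expected a 3-band image, got shape {arr.shape}"
        )
    geotransform = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        gt = meta.get("geotransform")
        if gt is not None:
            geotransform = tuple(float(v) for v in gt)
        date_label = date_label or meta.get("date_label", "")
    return RgbRaster(arr, geotransform=geotransform, date_label=date_label)


def write_raster(raster: RgbRaster, path: str | Path) -> Path:
    """Write a raster as TIFF (uint8 images, float32 maps) plus JSON sidecar."""
    path = Path(path)
    arr = raster.pixels
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    tifffile.imwrite(path, arr, photometric="rgb")
    if raster.geotransform is not None or raster.date_label:
        meta = {
            "geotransform": list(raster.geotransform) if raster.geotransform else None,
            "date_label": raster.date_label,
        }
        _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_rois(path: str | Path) -> list[PlotRoi]:
    """Read a JSON array of ``{plot_id, rect, treatment}`` records."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"ROI file not found: {path}")
    records = json.loads(path.read_text())
    rois = [
        PlotRoi(
            plot_id=str(rec["plot_id"]),
            rect=tuple(int(v) for v in rec["rect"]),
            treatment=rec.get("treatment"),
        )
        for rec in records
    ]
    seen: set[str] = set()
    for roi in rois:
        if roi.plot_id in seen:
            raise ValueError(f"duplicate plot_id {roi.plot_id!r} in {path}")
        seen.add(roi.plot_id)
    return rois


def write_rois(rois: Sequence[PlotRoi], path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {"plot_id": r.plot_id, "rect": list(r.rect), "treatment": r.treatment}
        for r in rois
    ]
    path.write_text(json.dumps(payload, indent=1))
    return path


def extract_subsamples(
    rasters: Iterable[RgbRaster], rois: Sequence[PlotRoi]
) -> list[tuple[str, str, RgbRaster]]:
    """Crop every ROI out of every raster.

    Returns ``len(rasters) × len(rois)`` tuples ``(plot_id, date_label,
    subsample)``, the per-plot per-date subsample images the plot statistics
    are computed on.  A ROI extending beyond any raster raises ``ValueError``
    naming the plot and date.
    """
    out: list[tuple[str, str, RgbRaster]] = []
    for raster in rasters:
        h, w = raster.shape
        for roi in rois:
            r0, c0, r1, c1 = roi.rect
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ValueError(
                    f"ROI {roi.plot_id!r} rect {roi.rect} outside raster "
                    f"{raster.date_label!r} of shape {(h, w)}"
                )
            out.append((roi.plot_id, raster.date_label, raster.crop(roi.rect)))
    return out
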