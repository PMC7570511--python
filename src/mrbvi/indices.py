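"""Chromatic-coordinate normalization and RGB vegetation indices.

Digital numbers are first reduced to chromatic coordinates

    R = r / (r + g + b),  G = g / (r + g + b),  B = b / (r + g + b),

which removes per-pixel brightness and leaves color composition (each valid
pixel's triplet sums to 1).  Eight indices are then available, including the
modified red–blue vegetation index

    MRBVI = (R² − B²) / (R² + B²),

a chlorophyll proxy driven by the red/blue contrast of the canopy.  The
others are the classic RGB indices ExR, NGBDI, COM1, ExB, WI, IKAW and CIVE.
Pixels where an index's denominator vanishes are masked invalid rather than
filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "IndexId",
    "ChromaticImage",
    "IndexMap",
    "normalize_bands",
    "compute_index",
    "ALL_INDICES",
    "DEFAULT_COM1_K",
]

DEFAULT_COM1_K = 0.667  # exponent k in COM1 = G / (R^k · B^(1-k))


class IndexId(str, Enum):
    """The eight supported RGB vegetation indices."""

    E1_EXR = "E1_EXR"
    E2_NGBDI = "E2_NGBDI"
    E3_COM1 = "E3_COM1"
    E4_EXB = "E4_EXB"
    E5_WI = "E5_WI"
    E6_IKAW = "E6_IKAW"
    E7_CIVE = "E7_CIVE"
    E8_MRBVI = "E8_MRBVI"

    @property
    def short_name(self) -> str:
        return self.value.split("_", 1)[1]


ALL_INDICES: tuple[IndexId, ...] = tuple(IndexId)


@dataclass
class ChromaticImage:
    """Per-pixel normalized band triplet with a validity mask.

    ``R + G + B == 1`` wherever ``valid_mask`` is true; pixels with zero
    band sum (r + g + b = 0) are invalid and carry NaN in all three bands.
    """

    R: np.ndarray
    G: np.ndarray
    B: np.ndarray
    valid_mask: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.R.shape


@dataclass
class IndexMap:
    """A per-pixel vegetation-index field with propagated validity."""

    values: np.ndarray
    valid_mask: np.ndarray
    index: IndexId


def normalize_bands(img) -> ChromaticImage:
    """Convert digital numbers to chromatic coordinates.

    Accepts an ``RgbRaster`` or a bare ``(..., 3)`` array of non-negative
    digital numbers.  The output is invariant to any positive per-pixel
    brightness scaling of the input.  Pixels with ``r + g + b == 0`` are
    masked invalid.
    """
    pixels = np.asarray(getattr(img, "pixels", img), dtype=np.float64)
    if pixels.shape[-1] != 3:
        raise ValueError(f"expected (..., 3) band array, got shape {pixels.shape}")
    if np.any(pixels < 0):
        raise ValueError("digital numbers must be non-negative")
    total = pixels.sum(axis=-1)
    valid = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        chrom = pixels / total[..., None]
    chrom[~valid] = np.nan
    return ChromaticImage(
        R=chrom[..., 0], G=chrom[..., 1], B=chrom[..., 2], valid_mask=valid
    )


# WI pixels closer than this to the R == G singularity are masked invalid.
_WI_EPS = 1e-9


def compute_index(
    chrom: ChromaticImage, index: IndexId | str, k: float = DEFAULT_COM1_K
) -> IndexMap:
    """Evaluate one vegetation index on a chromatic image.

    ``k`` is the COM1 exponent and must lie in (0, 1); it is ignored by the
    other indices.  Pixels where the formula is undefined (zero denominator,
    or the WI singularity ``R == G``) are masked invalid in the result.
    """
    index = IndexId(index)
    if not 0.0 < k < 1.0:
        raise ValueError(f"COM1 exponent k must be in (0, 1); got {k}")
    R, G, B = chrom.R, chrom.G, chrom.B
    valid = chrom.valid_mask.copy()

    with np.errstate(invalid="ignore", divide="ignore"):
        if index is IndexId.E1_EXR:
            values = 1.4 * R - G
        elif index is IndexId.E2_NGBDI:
            denom = G + B
            valid &= denom != 0
            values = (G - B) / denom
        elif index is IndexId.E3_COM1:
            valid &= (R > 0) & (B > 0)
            values = G / (R**k * B ** (1.0 - k))
        elif index is IndexId.E4_EXB:
            values = 1.4 * B - G
        elif index is IndexId.E5_WI:
            denom = R - G
            valid &= np.abs(denom) >= _WI_EPS
            values = (G - B) / denom
        elif index is IndexId.E6_IKAW:
            denom = R + B
            valid &= denom != 0
            values = (R - B) / denom
        elif index is IndexId.E7_CIVE:
            values = 0.441 * R - 0.811 * G + 0.385 * B + 18.787
        elif index is IndexId.E8_MRBVI:
            denom = R**2 + B**2
            valid &= denom != 0
            values = (R**2 - B**2) / denom
        else:  # pragma: no cover - enum is exhaustive
            raise ValueError(f"unknown index {index!r}")

    values = np.where(valid, values, np.nan)
    return IndexMap(values=values, valid_mask=valid, index=index)
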