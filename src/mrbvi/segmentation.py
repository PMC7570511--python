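"""Green-canopy segmentation by the ExG − ExR criterion.

A pixel is classified as vegetation when excess green exceeds excess red:

    ExG − ExR = (2G − R − B) − (1.4R − G) = 3G − 2.4R − B > threshold,

with the classic fixed threshold of 0 (the natural sign boundary).  No
morphological cleanup is applied; plot-level statistics are means over
thousands of pixels and are robust to isolated misclassifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .indices import ChromaticImage

__all__ = ["GreenMask", "green_mask", "exg_minus_exr"]


@dataclass
class GreenMask:
    """Boolean canopy mask derived from a chromatic image."""

    mask: np.ndarray
    source: ChromaticImage
    green_fraction: float  # fraction of *valid* pixels flagged green


def exg_minus_exr(chrom: ChromaticImage) -> np.ndarray:
    """Per-pixel ExG − ExR decision value (NaN on invalid pixels)."""
    return (2.0 * chrom.G - chrom.R - chrom.B) - (1.4 * chrom.R - chrom.G)


def green_mask(chrom: ChromaticImage, threshold: float = 0.0) -> GreenMask:
    """Flag pixels with ExG − ExR strictly above ``threshold`` as canopy.

    Invalid source pixels are never green.  ``green_fraction`` is the share
    of valid pixels classified green (0 when no pixel is valid).
    """
    decision = exg_minus_exr(chrom)
    with np.errstate(invalid="ignore"):
        mask = (decision > threshold) & chrom.valid_mask
    n_valid = int(chrom.valid_mask.sum())
    fraction = float(mask.sum() / n_valid) if n_valid else 0.0
    return GreenMask(mask=mask, source=chrom, green_fraction=fraction)
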