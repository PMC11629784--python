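"""Background correction, dynamic-range standardization and normalization.

The correction chain assumes stitched, cycle-aligned stacks (stitching
and registration are upstream concerns):

1. subtract the matching blank-cycle channel from each stained channel
   (autofluorescence removal), clipping at zero;
2. divide by the standard deviation of that blank channel, so channels
   acquired at different excitation wavelengths — which have different
   dynamic ranges — are put on a comparable scale;
3. min–max normalize each channel to its 99th percentile, clipping the
   top 1% of pixels to 1, which maps intensities onto the [0, 1] range of
   the reference pseudo-spectra.

A tissue mask separates section from bare slide so that pixel-level
summaries are computed over tissue only.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk, remove_small_objects

from .image import BlankStack, MultiplexImage, TissueMask

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 99.0
DEFAULT_CLOSE_RADIUS = 5
DEFAULT_MIN_OBJECT = 64


def background_correct(stained: MultiplexImage, blank: BlankStack) -> MultiplexImage:
    """Subtract the blank cycle and standardize by its per-channel SD.

    Each stained channel is paired with the blank channel sharing its
    excitation-wavelength tag (falling back to positional pairing when
    the image carries no tags).  Output channel ``c`` is::

        clip(stained[c] - blank_for(c), 0, None) / std(blank_for(c))

    Negative differences are clipped to zero: intensities are physically
    non-negative and the cosine mapping assumes non-negative vectors.
    """
    if stained.shape != blank.shape:
        raise ValueError(
            f"spatial shape mismatch: stained {stained.shape} vs blank {blank.shape}"
        )
    tags = stained.channel_wavelengths
    if tags is None:
        if stained.n_channels != blank.data.shape[0]:
            raise ValueError(
                "image has no wavelength tags and channel counts differ; "
                "cannot pair blank channels positionally"
            )
        blank_channels = [blank.data[c] for c in range(stained.n_channels)]
    else:
        blank_channels = [blank.channel_for(t) for t in tags]

    out = np.empty_like(stained.data, dtype=np.float32)
    for c, bg in enumerate(blank_channels):
        sd = float(np.std(bg))
        if sd == 0:
            raise ValueError(
                f"blank channel for {stained.channel_names[c]!r} has zero "
                "variance; cannot standardize dynamic range"
            )
        out[c] = np.clip(stained.data[c] - bg, 0, None) / sd
    return stained.with_data(out)


def normalize_channels(
    img: MultiplexImage, percentile: float = DEFAULT_PERCENTILE
) -> MultiplexImage:
    """Per-channel min–max normalization to the given upper percentile.

    Values map as ``(v - min) / (P - min)`` clipped to [0, 1], where P is
    the channel's ``percentile`` value; the brightest pixels above P
    saturate at 1.  A degenerate channel (P == min) becomes all zeros with
    a warning.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    out = np.empty_like(img.data, dtype=np.float32)
    for c in range(img.n_channels):
        channel = img.data[c]
        lo = float(channel.min())
        hi = float(np.percentile(channel, percentile))
        if hi <= lo:
            logger.warning(
                "channel %r is degenerate (P%g == min == %g); set to 0",
                img.channel_names[c], percentile, lo,
            )
            out[c] = 0.0
        else:
            out[c] = np.clip((channel - lo) / (hi - lo), 0.0, 1.0)
    return img.with_data(out)


def compute_tissue_mask(
    img: MultiplexImage,
    close_radius: int = DEFAULT_CLOSE_RADIUS,
    min_object: int = DEFAULT_MIN_OBJECT,
) -> TissueMask:
    """Separate tissue from bare slide.

    Otsu-thresholds the across-channel intensity sum, then closes small
    gaps (binary closing with a disc of ``close_radius``) and removes
    specks below ``min_object`` pixels.  An all-zero image yields an empty
    mask.
    """
    total = img.data.sum(axis=0)
    lo, hi = float(total.min()), float(total.max())
    if hi == lo:
        # Constant sum: all-tissue if bright, empty if dark.
        mask = np.full(total.shape, hi > 0, dtype=bool)
        if not mask.any():
            logger.warning("tissue mask is empty (constant zero image)")
        return TissueMask(mask)
    mask = total > threshold_otsu(total)
    if close_radius > 0:
        mask = ndi.binary_closing(mask, structure=disk(close_radius))
    if min_object > 1:
        # remove objects strictly smaller than min_object pixels
        mask = remove_small_objects(mask, max_size=min_object - 1)
    if not mask.any():
        logger.warning("tissue mask is empty after morphology")
    return TissueMask(mask)
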