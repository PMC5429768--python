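"""Mask operators: regions of interest on a single-cell channel image.

Imaging-flow-cytometry features are computed over a *mask* — a boolean
raster delineating the staining of interest.  Two operators cover the
needs of the Golgi-fragmentation pipeline:

* :func:`object_mask` — an Otsu-thresholded "object" mask of a channel,
  optionally restricted to the largest connected component (used for the
  bright-field cell outline) or keeping every stained component (used for
  the Golgi and DNA staining, which may be fragmented by construction).
* :func:`threshold_mask` — the percentile mask central to the method: the
  p% highest-intensity pixels of a parent mask (e.g. Threshold_60 of the
  Golgi staining, Threshold_50 of the DNA staining).

All connectivity is 8-connected; percentile selection is by pixel count
with ties broken in row-major order, so masks are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "Mask",
    "object_mask",
    "threshold_mask",
    "count_components",
    "STRUCT8",
]

#: 3x3 structuring element giving 8-connectivity everywhere in the package.
STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Mask:
    """Boolean region of interest aligned to a cell's channel rasters.

    Parameters
    ----------
    raster
        Boolean 2-D array, same shape as the channels it refers to.
    channel
        Name of the channel the mask was derived from ("" if synthetic).
    recipe
        Human-readable recipe string, e.g. ``"Threshold(Object(GOLGI,all),GOLGI,60)"``;
        stored in feature-table provenance so a mask can be rebuilt from
        its cell record.
    """

    raster: np.ndarray
    channel: str = ""
    recipe: str = ""

    def __post_init__(self) -> None:
        raster = np.asarray(self.raster, dtype=bool)
        object.__setattr__(self, "raster", raster)
        if raster.ndim != 2:
            raise ValueError("mask raster must be 2-D")

    @property
    def size(self) -> int:
        """Number of pixels in the mask."""
        return int(self.raster.sum())

    @property
    def is_empty(self) -> bool:
        return not self.raster.any()

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape  # type: ignore[return-value]

    def indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column indices of in-mask pixels, in row-major order."""
        return np.nonzero(self.raster)


def object_mask(
    channel: np.ndarray,
    channel_name: str = "",
    keep: str = "largest",
) -> Mask:
    """Otsu object mask of a channel raster.

    Thresholds the channel globally (Otsu), fills holes and, depending on
    ``keep``, retains either the largest 8-connected component
    (``"largest"``, appropriate for the single bright-field cell body) or
    all components (``"all"``, appropriate for fragmented staining such as
    dispersed Golgi vesicles or separated anaphase DNA masses).

    A raster with no pixel above threshold (including a constant raster)
    yields an empty mask — a valid, flagged result rather than an error.
    """
    if keep not in ("largest", "all"):
        raise ValueError(f"keep must be 'largest' or 'all', got {keep!r}")
    channel = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel raster contains non-finite values")
    recipe = f"Object({channel_name},{keep})" if keep == "all" else f"Object({channel_name})"
    if channel.max() == channel.min():
        return Mask(np.zeros(channel.shape, dtype=bool), channel_name, recipe)
    thr = threshold_otsu(channel)
    binary = channel > thr
    if not binary.any():
        return Mask(np.zeros(channel.shape, dtype=bool), channel_name, recipe)
    labels, n = ndimage.label(binary, structure=STRUCT8)
    if keep == "largest" and n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        binary = labels == int(np.argmax(counts))
    binary = ndimage.binary_fill_holes(binary, structure=STRUCT8)
    return Mask(binary, channel_name, recipe)


def threshold_mask(
    parent: Mask,
    channel: np.ndarray,
    p: float,
    mode: str = "pixel_count",
) -> Mask:
    """The p% highest-intensity pixels of ``channel`` within ``parent``.

    ``mode="pixel_count"`` (default, and the reading used throughout the
    pipeline) keeps ``k = ceil(p/100 * |parent|)`` pixels.  Ties at the
    cutoff intensity are resolved in row-major scan order so exactly ``k``
    pixels are kept and the result is platform-independent.

    ``mode="intensity"`` instead keeps the smallest top-intensity pixel
    set whose summed intensity reaches p% of the total in-parent
    intensity (the alternative reading of a percentile mask).

    The result is always a subset of ``parent``.
    """
    if not (0 < p <= 100):
        raise ValueError(f"percentage must be in (0, 100], got {p}")
    if mode not in ("pixel_count", "intensity"):
        raise ValueError(f"unknown threshold mode {mode!r}")
    if parent.is_empty:
        raise ValueError("threshold_mask requires a non-empty parent mask")
    channel = np.asarray(channel, dtype=float)
    if channel.shape != parent.shape:
        raise ValueError("channel and parent mask shapes differ")

    rows, cols = parent.indices()            # row-major order
    values = channel[rows, cols]
    order = np.argsort(-values, kind="stable")  # stable: ties keep row-major order

    if mode == "pixel_count":
        k = math.ceil(p / 100.0 * rows.size)
    else:
        total = float(values.sum())
        if total <= 0:
            k = rows.size
        else:
            csum = np.cumsum(values[order])
            k = int(np.searchsorted(csum, p / 100.0 * total)) + 1
            k = min(k, rows.size)

    sel = order[:k]
    raster = np.zeros(parent.shape, dtype=bool)
    raster[rows[sel], cols[sel]] = True
    suffix = "" if mode == "pixel_count" else ",intensity"
    recipe = f"Threshold({parent.recipe or '?'},{parent.channel or '?'},{p:g}{suffix})"
    return Mask(raster, parent.channel, recipe)


def count_components(mask: Mask) -> int:
    """Number of 8-connected components of a mask (0 for an empty mask)."""
    if mask.is_empty:
        return 0
    _, n = ndimage.label(mask.raster, structure=STRUCT8)
    return int(n)
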