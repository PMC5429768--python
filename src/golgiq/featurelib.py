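"""Per-cell feature computations.

Each feature is a scalar computed from a (channel, mask) pair of one
cell: mask area, intensity-weighted ellipse axes, image sharpness
(gradient RMS), brightness-normalized texture contrast, bright-detail
(top-hat) intensity and the PulSA pulse-shape triplet.  The headline
pair of the Golgi-fragmentation method is the *area* and the
*minor-axis intensity* of the Threshold-60 mask of the Golgi staining:
an intact, compact Golgi ribbon has a small area and a narrow
intensity-weighted ellipse, while dispersed vesicles of a fully
fragmented Golgi cover a large, round footprint.

Axis-length convention: the ellipse with the same second moments as the
(weighted) pixel distribution has semi-axes 2*sqrt(eigenvalue); axis
lengths here are 4*sqrt(eigenvalue) x pixel_size, i.e. the +/-2 sigma
diameter in μm.  The constant is frozen; it only rescales gate axes.

Invalid values (empty mask, zero in-mask intensity) are returned as NaN
and flagged, never raised, so one degenerate cell cannot abort a run.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk, opening

from .ifcio import CHANNELS, CellRecord, FeatureTable, GolgiqError, MaskParams
from .maskops import Mask, object_mask, threshold_mask

__all__ = [
    "Moments",
    "PulsaTriplet",
    "FeatureSpec",
    "area",
    "intensity_moments",
    "aspect_ratio",
    "gradient_rms",
    "bf_contrast",
    "bright_detail_intensity",
    "pulsa_triplet",
    "default_panel",
    "compute_feature_table",
    "build_mask",
]

_SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


# ---------------------------------------------------------------------------
# Elementary features
# ---------------------------------------------------------------------------


def area(mask: Mask, pixel_size: float) -> float:
    """Mask area in μm²: pixel count × pixel_size²  (empty mask → 0)."""
    return mask.size * pixel_size**2


class Moments(NamedTuple):
    """Intensity-weighted moment summary of a masked signal."""

    total_intensity: float
    centroid: tuple[float, float]  # (row, col), px
    minor_axis_um: float
    major_axis_um: float


def _weighted_axes(rows: np.ndarray, cols: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Ellipse eigen-axes (λ2, λ1) of the weighted second-central-moment matrix."""
    total = w.sum()
    rc = float((w * rows).sum() / total)
    cc = float((w * cols).sum() / total)
    dr = rows - rc
    dc = cols - cc
    mrr = float((w * dr * dr).sum() / total)
    mcc = float((w * dc * dc).sum() / total)
    mrc = float((w * dr * dc).sum() / total)
    half_tr = 0.5 * (mrr + mcc)
    disc = math.sqrt(max(half_tr**2 - (mrr * mcc - mrc**2), 0.0))
    lam1 = half_tr + disc
    lam2 = max(half_tr - disc, 0.0)
    return lam2, lam1


def intensity_moments(channel: np.ndarray, mask: Mask, pixel_size: float) -> Moments:
    """Total intensity, weighted centroid and ellipse axes of a masked signal.

    Weights are the in-mask channel intensities.  A zero total intensity
    (or empty mask) yields NaN axes — a flagged-invalid value for the
    cell, not an exception.
    """
    channel = np.asarray(channel, dtype=float)
    if mask.is_empty:
        return Moments(0.0, (math.nan, math.nan), math.nan, math.nan)
    rows, cols = mask.indices()
    w = channel[rows, cols]
    total = float(w.sum())
    if total <= 0:
        return Moments(total, (math.nan, math.nan), math.nan, math.nan)
    rc = float((w * rows).sum() / total)
    cc = float((w * cols).sum() / total)
    lam2, lam1 = _weighted_axes(rows.astype(float), cols.astype(float), w)
    return Moments(total, (rc, cc), 4.0 * math.sqrt(lam2) * pixel_size, 4.0 * math.sqrt(lam1) * pixel_size)


def aspect_ratio(mask: Mask) -> float:
    """Binary (unweighted) minor/major axis ratio in (0, 1].

    Uses the same moment construction with unit weights; a single-pixel
    (or otherwise degenerate point-like) mask returns 1 by convention.
    """
    if mask.is_empty:
        return math.nan
    rows, cols = mask.indices()
    if rows.size == 1:
        return 1.0
    w = np.ones(rows.size)
    lam2, lam1 = _weighted_axes(rows.astype(float), cols.astype(float), w)
    if lam1 <= 0:
        return 1.0
    return math.sqrt(lam2 / lam1)


def gradient_rms(channel: np.ndarray, mask: Mask) -> float:
    """Root-mean-square 3x3 Sobel gradient magnitude over in-mask pixels.

    An image-sharpness measure: defocused cells have weak gradients.
    """
    if mask.is_empty:
        return math.nan
    channel = np.asarray(channel, dtype=float)
    gx = ndimage.convolve(channel, _SOBEL_X, mode="reflect")
    gy = ndimage.convolve(channel, _SOBEL_Y, mode="reflect")
    mag2 = gx**2 + gy**2
    return math.sqrt(float(mag2[mask.raster].mean()))


def bf_contrast(channel: np.ndarray, mask: Mask) -> float:
    """Brightness-normalized texture contrast: gradient RMS / mean intensity.

    Scale-invariant by construction, so overall illumination changes
    cancel; high for the speckled bright-field texture of apoptotic
    cells.  Zero or negative mean intensity → NaN (flagged invalid).
    """
    if mask.is_empty:
        return math.nan
    channel = np.asarray(channel, dtype=float)
    mean = float(channel[mask.raster].mean())
    if mean <= 0:
        return math.nan
    return gradient_rms(channel, mask) / mean


def bright_detail_intensity(channel: np.ndarray, mask: Mask, radius: int = 3) -> float:
    """Summed intensity of small bright features after local-background removal.

    Top-hat style: the channel minus its grayscale opening with a disk of
    the given radius, clipped at zero, summed over the mask.  Features
    wider than the structuring element survive the opening and contribute
    ~nothing; condensed or speckled nuclei score high.
    """
    if radius < 1:
        raise ValueError("bright-detail radius must be >= 1 px")
    if mask.is_empty:
        return 0.0
    channel = np.asarray(channel, dtype=float)
    residual = np.maximum(channel - opening(channel, disk(radius)), 0.0)
    return float(residual[mask.raster].sum())


@dataclass(frozen=True)
class PulsaTriplet:
    """Pulse-shape analysis triplet of the projected Golgi signal.

    The in-mask intensity is projected onto the x axis (column sums),
    emulating the pulse a conventional cytometer records as the cell
    transits the laser: height = profile maximum (au), area = profile sum
    (au), width = full width at half maximum (μm; count of columns at or
    above half the peak).
    """

    area: float
    width_um: float
    height: float
    valid: bool = True


def pulsa_triplet(channel: np.ndarray, mask: Mask, pixel_size: float) -> PulsaTriplet:
    if mask.is_empty:
        return PulsaTriplet(0.0, 0.0, 0.0, valid=False)
    channel = np.asarray(channel, dtype=float)
    profile = np.where(mask.raster, channel, 0.0).sum(axis=0)
    height = float(profile.max())
    if height <= 0:
        return PulsaTriplet(0.0, 0.0, 0.0, valid=False)
    width = int((profile >= 0.5 * height).sum()) * pixel_size
    return PulsaTriplet(float(profile.sum()), width, height)


# ---------------------------------------------------------------------------
# Mask recipes
# ---------------------------------------------------------------------------

_RECIPE_RE = re.compile(r"^(?P<op>All|Object|Threshold)\((?P<args>.*)\)$")


def _split_args(args: str) -> list[str]:
    """Split a recipe argument list at top-level commas."""
    parts, depth, cur = [], 0, []
    for ch in args:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if cur or parts:
        parts.append("".join(cur))
    return [p.strip() for p in parts]


def build_mask(recipe: str, cell: CellRecord, mode: str = "pixel_count") -> Mask:
    """Build a mask from its recipe string against a cell record.

    Grammar::

        All()                          whole frame
        Object(CH)                     Otsu object mask, largest component
        Object(CH,all)                 Otsu object mask, all components
        Threshold(<mask>,CH,p)         p% highest-intensity pixels of <mask>

    An empty parent makes the Threshold result empty (rather than an
    error) so that a cell with no detectable staining yields area 0 and
    flagged intensity features instead of aborting a batch.
    """
    m = _RECIPE_RE.match(recipe.strip())
    if m is None:
        raise GolgiqError(f"unparseable mask recipe: {recipe!r}")
    op = m.group("op")
    args = _split_args(m.group("args"))
    if op == "All":
        shape = cell.shape
        return Mask(np.ones(shape, dtype=bool), "", "All()")
    if op == "Object":
        if len(args) not in (1, 2):
            raise GolgiqError(f"Object() takes 1-2 arguments: {recipe!r}")
        ch = args[0]
        if ch not in CHANNELS:
            raise GolgiqError(f"unknown channel {ch!r} in recipe {recipe!r}")
        keep = args[1] if len(args) == 2 else "largest"
        return object_mask(cell.channels[ch], ch, keep=keep)
    # Threshold
    if len(args) != 3:
        raise GolgiqError(f"Threshold() takes 3 arguments: {recipe!r}")
    parent = build_mask(args[0], cell, mode=mode)
    ch = args[1]
    if ch not in CHANNELS:
        raise GolgiqError(f"unknown channel {ch!r} in recipe {recipe!r}")
    p = float(args[2])
    if parent.is_empty:
        return Mask(np.zeros(cell.shape, dtype=bool), ch, recipe)
    return threshold_mask(parent, cell.channels[ch], p, mode=mode)


# ---------------------------------------------------------------------------
# Feature specs and the default panel
# ---------------------------------------------------------------------------

_OPS = (
    "area",
    "total_intensity",
    "minor_axis_intensity",
    "major_axis_intensity",
    "aspect_ratio",
    "gradient_rms",
    "contrast",
    "bright_detail",
    "pulsa_area",
    "pulsa_width",
    "pulsa_height",
)

_UNITS = {
    "area": "um2",
    "total_intensity": "au",
    "minor_axis_intensity": "um",
    "major_axis_intensity": "um",
    "aspect_ratio": "ratio",
    "gradient_rms": "au",
    "contrast": "ratio",
    "bright_detail": "au",
    "pulsa_area": "au",
    "pulsa_width": "um",
    "pulsa_height": "au",
}


@dataclass(frozen=True)
class FeatureSpec:
    """One named feature: an operation on a (channel, mask-recipe) pair."""

    name: str
    op: str
    channel: str
    mask_recipe: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise GolgiqError(f"unknown feature op {self.op!r} (feature {self.name!r})")
        if self.channel not in CHANNELS:
            raise GolgiqError(f"unknown channel {self.channel!r} (feature {self.name!r})")

    @property
    def unit(self) -> str:
        return _UNITS[self.op]


def default_panel(mask_params: MaskParams | None = None) -> list[FeatureSpec]:
    """The standard feature panel of the pipeline.

    Golgi Threshold-60 area and minor-axis intensity (the fragmentation
    readout), BF object area / aspect ratio (singlet gate), BF gradient
    RMS (focus gate), BF contrast (apoptosis gate), DNA total intensity
    (cell cycle), DNA bright-detail intensity and Threshold-50 DNA area
    (mitotic sub-phases, apoptosis), and the PulSA triplet of the Golgi
    channel as comparison baseline.
    """
    mp = mask_params or MaskParams()
    golgi_parent = "Object(GOLGI,all)"
    dna_parent = "Object(DNA,all)"
    golgi_t = f"Threshold({golgi_parent},GOLGI,{mp.golgi_threshold_pct:g})"
    dna_t = f"Threshold({dna_parent},DNA,{mp.dna_threshold_pct:g})"
    r = mp.bright_detail_radius_px
    return [
        FeatureSpec("golgi_t60_area", "area", "GOLGI", golgi_t),
        FeatureSpec("golgi_t60_minor_axis_intensity", "minor_axis_intensity", "GOLGI", golgi_t),
        FeatureSpec("bf_object_area", "area", "BF", "Object(BF)"),
        FeatureSpec("bf_aspect_ratio", "aspect_ratio", "BF", "Object(BF)"),
        FeatureSpec("bf_gradient_rms", "gradient_rms", "BF", "Object(BF)"),
        FeatureSpec("bf_contrast", "contrast", "BF", "Object(BF)"),
        FeatureSpec("dna_total_intensity", "total_intensity", "DNA", dna_parent),
        FeatureSpec(f"dna_bdi_r{r}", "bright_detail", "DNA", dna_parent, {"radius": r}),
        FeatureSpec("dna_t50_area", "area", "DNA", dna_t),
        FeatureSpec("pulsa_area", "pulsa_area", "GOLGI", "All()"),
        FeatureSpec("pulsa_width", "pulsa_width", "GOLGI", "All()"),
        FeatureSpec("pulsa_height", "pulsa_height", "GOLGI", "All()"),
    ]


def _evaluate(spec: FeatureSpec, cell: CellRecord, mask: Mask) -> float:
    ch = cell.channels[spec.channel]
    if spec.op == "area":
        return area(mask, cell.pixel_size)
    if spec.op == "total_intensity":
        return intensity_moments(ch, mask, cell.pixel_size).total_intensity
    if spec.op == "minor_axis_intensity":
        return intensity_moments(ch, mask, cell.pixel_size).minor_axis_um
    if spec.op == "major_axis_intensity":
        return intensity_moments(ch, mask, cell.pixel_size).major_axis_um
    if spec.op == "aspect_ratio":
        return aspect_ratio(mask)
    if spec.op == "gradient_rms":
        return gradient_rms(ch, mask)
    if spec.op == "contrast":
        return bf_contrast(ch, mask)
    if spec.op == "bright_detail":
        return bright_detail_intensity(ch, mask, int(spec.params.get("radius", 3)))
    triplet = pulsa_triplet(ch, mask, cell.pixel_size)
    if spec.op == "pulsa_area":
        return triplet.area
    if spec.op == "pulsa_width":
        return triplet.width_um
    return triplet.height


def compute_feature_table(
    cells: Sequence[CellRecord] | Iterable[CellRecord],
    specs: Sequence[FeatureSpec] | None = None,
    mask_params: MaskParams | None = None,
) -> FeatureTable:
    """Compute the feature table for a list of cells.

    One row per cell, in input order; invalid values are NaN, never
    dropped; deterministic.  Spec validation (unknown ops, channels)
    happens in :class:`FeatureSpec` construction, before any pixel work.
    """
    mp = mask_params or MaskParams()
    if specs is None:
        specs = default_panel(mp)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise GolgiqError(f"duplicate feature names in panel: {names}")

    cells = list(cells)
    rows = np.full((len(cells), len(specs)), np.nan)
    for i, cell in enumerate(cells):
        mask_cache: dict[str, Mask] = {}
        for j, spec in enumerate(specs):
            mask = mask_cache.get(spec.mask_recipe)
            if mask is None:
                mask = build_mask(spec.mask_recipe, cell, mode=mp.threshold_mode)
                mask_cache[spec.mask_recipe] = mask
            rows[i, j] = _evaluate(spec, cell, mask)
    df = pd.DataFrame(rows, index=pd.Index([c.cell_id for c in cells], name="cell_id"), columns=names)
    provenance = {
        s.name: {
            "channel": s.channel,
            "mask": s.mask_recipe,
            "op": s.op,
            "params": dict(s.params),
            "unit": s.unit,
        }
        for s in specs
    }
    return FeatureTable(df, provenance)
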