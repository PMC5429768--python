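"""Hierarchical gating, Golgi-morphology classification and feature selection.

The gating hierarchy mirrors standard imaging-flow-cytometry practice:

1. **singlets** — bright-field object area within a range and aspect
   ratio above a minimum (rejects doublets and debris);
2. **focused** — bright-field gradient RMS above a minimum;
3. **DNA content** — G1 / S-indeterminate / G2M windows relative to the
   2N (G1) mode of the DNA total-intensity histogram;
4. **mitotic sub-phases** — within G2M, a rule cascade on DNA
   bright-detail intensity, Threshold-50 DNA area and nuclear-mass
   component count/separation (prophase / metaphase / anaphase / telophase);
5. **apoptosis** — high bright-field contrast plus condensed (small)
   Threshold-50 DNA area;
6. **Golgi morphology** — intact / partial / full regions on the plane
   (Threshold-60 minor-axis intensity, Threshold-60 area).

Feature selection uses Fisher's discriminant ratio
``RD = (mean_b - mean_a) / (sd_a + sd_b)`` to rank features by how well
they separate two labeled populations — the criterion that singles out
the Threshold-60 area / minor-axis-intensity pair in the first place.

Gate boundaries between adjacent classes sit at the variance-weighted
midpoint ``t = (mu1*sd2 + mu2*sd1) / (sd1 + sd2)`` of the class
calibration statistics; boundaries are closed below / open above, so a
point exactly on a threshold belongs to the lower region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .ifcio import (
    CellRecord,
    FeatureTable,
    GateConfig,
    GolgiRegionConfig,
    GolgiqError,
    ValidationError,
)
from .maskops import STRUCT8, object_mask

__all__ = [
    "GOLGI_LABELS",
    "rd_value",
    "RDRanking",
    "rank_features",
    "GolgiGates",
    "fit_golgi_gates",
    "classify_golgi",
    "gate_singlets_focused",
    "gate_dna_content",
    "classify_mitotic",
    "gate_apoptotic",
    "GatingResult",
    "run_gating",
    "calibrate_gate_config",
]

GOLGI_LABELS = ("intact", "partial", "full")
CYCLE_LABELS = ("G1", "S/indeterminate", "G2M", "excluded")
MITOTIC_LABELS = ("none", "prophase", "metaphase", "anaphase", "telophase")


# ---------------------------------------------------------------------------
# Fisher's discriminant (RD) feature selection
# ---------------------------------------------------------------------------


def rd_value(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Fisher's discriminant ratio: (mean_b - mean_a) / (sd_a + sd_b).

    Sample standard deviations (ddof=1).  Sign is kept (positive when b
    sits above a); |RD| is what rankings sort by.  Two degenerate
    point-mass populations give 0 when their means agree and +/-inf
    (flagged infinite separation) when they do not.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("rd_value requires >= 2 values per population")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("rd_value requires finite values")
    denom = a.std(ddof=1) + b.std(ddof=1)
    diff = b.mean() - a.mean()
    if denom == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / denom)


@dataclass(frozen=True)
class RDRanking:
    """Features ranked by |RD| for one two-class comparison."""

    class_a: str
    class_b: str
    entries: list[tuple[str, float]]  # (feature name, signed RD), descending |RD|
    n_excluded: dict[str, int] = field(default_factory=dict)  # invalid cells per feature

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.entries[:k]]

    def __getitem__(self, feature: str) -> float:
        for name, rd in self.entries:
            if name == feature:
                return rd
        raise KeyError(feature)


def rank_features(table: FeatureTable, labels: pd.Series | Mapping[str, str]) -> RDRanking:
    """Rank every feature column by |RD| between two labeled classes.

    ``labels`` maps cell_id → class for exactly two classes (class order
    a/b is alphabetical, fixing the RD sign convention).  Cells with a
    flagged-invalid (NaN) value are excluded pairwise for that feature
    and counted in ``n_excluded``.  Ties in |RD| break by feature name.
    """
    labels = pd.Series(labels)
    labels = labels[labels.index.isin(table.df.index)]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValidationError(f"rank_features needs exactly 2 classes, got {classes}")
    a_ids = labels.index[labels == classes[0]]
    b_ids = labels.index[labels == classes[1]]
    entries: list[tuple[str, float]] = []
    n_excluded: dict[str, int] = {}
    for name in table.feature_names:
        col = table.df[name]
        a = col.loc[a_ids]
        b = col.loc[b_ids]
        bad = int(a.isna().sum() + b.isna().sum())
        if bad:
            n_excluded[name] = bad
        a = a.dropna()
        b = b.dropna()
        if len(a) < 2 or len(b) < 2:
            entries.append((name, math.nan))
            continue
        entries.append((name, rd_value(a.to_numpy(), b.to_numpy())))
    entries.sort(key=lambda e: (-(abs(e[1]) if np.isfinite(e[1]) else math.inf
                                  if not math.isnan(e[1]) else -math.inf), e[0]))
    return RDRanking(classes[0], classes[1], entries, n_excluded)


# ---------------------------------------------------------------------------
# Golgi morphology gates
# ---------------------------------------------------------------------------


def _vw_midpoint(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Variance-weighted midpoint between two class distributions.

    Reduces to the arithmetic midpoint when sd1 == sd2 (including both 0).
    """
    if sd1 + sd2 == 0:
        return 0.5 * (mu1 + mu2)
    return (mu1 * sd2 + mu2 * sd1) / (sd1 + sd2)


@dataclass(frozen=True)
class GolgiGates:
    """Intact / partial / full decision regions on the fragmentation plane.

    x = Threshold-60 minor-axis intensity (μm), y = Threshold-60 area
    (μm²).  Rectangular form: intact occupies the closed lower-left
    corner (x <= intact_max_x and y <= intact_max_y), full the open
    upper-right corner (x > full_min_x and y > full_min_y), partial the
    complement — a partition of the quadrant by construction.  Polygon
    gates (hand-drawn replicas) classify by containment with
    nearest-region fallback, preserving the partition.
    """

    x_feature: str = "golgi_t60_minor_axis_intensity"
    y_feature: str = "golgi_t60_area"
    intact_max: tuple[float, float] = (1.9, 5.9)
    full_min: tuple[float, float] = (8.8, 16.1)
    polygons: dict[str, list[list[float]]] | None = None

    def classify_point(self, x: float, y: float) -> str:
        """Label a single (x, y) point; NaN input → 'unassigned'."""
        if not (np.isfinite(x) and np.isfinite(y)):
            return "unassigned"
        if self.polygons is not None:
            return self._classify_polygon(x, y)
        if x <= self.intact_max[0] and y <= self.intact_max[1]:
            return "intact"
        if x > self.full_min[0] and y > self.full_min[1]:
            return "full"
        return "partial"

    def _classify_polygon(self, x: float, y: float) -> str:
        from shapely.geometry import Point, Polygon

        pt = Point(x, y)
        polys = {k: Polygon(v) for k, v in self.polygons.items()}  # type: ignore[union-attr]
        containing = [k for k in GOLGI_LABELS if polys[k].covers(pt)]
        if containing:
            return containing[0]  # boundary ties go to the lower class
        dists = {k: polys[k].distance(pt) for k in GOLGI_LABELS}
        return min(GOLGI_LABELS, key=lambda k: (dists[k], GOLGI_LABELS.index(k)))

    def classify(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized labels for arrays of (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.polygons is not None:
            return np.array([self.classify_point(xi, yi) for xi, yi in zip(x, y)])
        out = np.full(x.shape, "partial", dtype=object)
        finite = np.isfinite(x) & np.isfinite(y)
        intact = finite & (x <= self.intact_max[0]) & (y <= self.intact_max[1])
        full = finite & (x > self.full_min[0]) & (y > self.full_min[1])
        out[intact] = "intact"
        out[full] = "full"
        out[~finite] = "unassigned"
        return out

    def to_config(self) -> GolgiRegionConfig:
        cfg = GolgiRegionConfig(
            x_feature=self.x_feature,
            y_feature=self.y_feature,
            intact_max=tuple(self.intact_max),
            full_min=tuple(self.full_min),
            polygons=self.polygons,
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_config(cls, cfg: GolgiRegionConfig) -> "GolgiGates":
        cfg.validate()
        return cls(
            x_feature=cfg.x_feature,
            y_feature=cfg.y_feature,
            intact_max=tuple(cfg.intact_max),
            full_min=tuple(cfg.full_min),
            polygons=cfg.polygons,
        )


def fit_golgi_gates(
    table: FeatureTable,
    labels: pd.Series | Mapping[str, str],
    x_feature: str = "golgi_t60_minor_axis_intensity",
    y_feature: str = "golgi_t60_area",
) -> GolgiGates:
    """Calibrate intact/partial/full gates from labeled exemplar cells.

    Per class, computes mean and SD of (x, y); the boundary between
    adjacent classes on each axis is the variance-weighted midpoint.
    Requires >= 30 labeled cells per class and strictly ordered class
    means (intact < partial < full on both axes) — a synthetic stand-in
    for drawing gates around the center of each reference condition.
    """
    labels = pd.Series(labels)
    labels = labels[labels.index.isin(table.df.index)]
    stats: dict[str, dict[str, tuple[float, float]]] = {}
    for cls in GOLGI_LABELS:
        ids = labels.index[labels == cls]
        if len(ids) < 30:
            raise ValidationError(
                f"fit_golgi_gates needs >= 30 cells per class; {cls!r} has {len(ids)}"
            )
        sub = table.df.loc[ids, [x_feature, y_feature]].dropna()
        stats[cls] = {
            "x": (float(sub[x_feature].mean()), float(sub[x_feature].std(ddof=1))),
            "y": (float(sub[y_feature].mean()), float(sub[y_feature].std(ddof=1))),
        }
    for axis, feat in (("x", x_feature), ("y", y_feature)):
        m_i, m_p, m_f = (stats[c][axis][0] for c in GOLGI_LABELS)
        if not (m_i < m_p < m_f):
            raise ValidationError(
                f"class means not ordered intact < partial < full on the {axis} axis "
                f"({feat}): {m_i:.3g}, {m_p:.3g}, {m_f:.3g}"
            )
    t = {}
    for axis in ("x", "y"):
        mi, si = stats["intact"][axis]
        mp, sp = stats["partial"][axis]
        mf, sf = stats["full"][axis]
        t[axis] = (_vw_midpoint(mi, si, mp, sp), _vw_midpoint(mp, sp, mf, sf))
    return GolgiGates(
        x_feature=x_feature,
        y_feature=y_feature,
        intact_max=(t["x"][0], t["y"][0]),
        full_min=(t["x"][1], t["y"][1]),
    )


def classify_golgi(
    table: FeatureTable,
    gates: GolgiGates,
    eligible: pd.Series | None = None,
) -> tuple[pd.Series, dict[str, int]]:
    """Assign intact/partial/full to each eligible cell.

    ``eligible`` is a boolean series (singlet AND focused); ineligible
    cells are 'unassigned'.  Cells with flagged-invalid coordinates are
    'unassigned' and counted in the returned QC tally.
    """
    df = table.df
    for feat in (gates.x_feature, gates.y_feature):
        if feat not in df.columns:
            raise GolgiqError(f"feature table lacks column {feat!r}")
    if eligible is None:
        eligible = pd.Series(True, index=df.index)
    eligible = eligible.reindex(df.index, fill_value=False).astype(bool)
    labels = pd.Series("unassigned", index=df.index, dtype=object, name="golgi")
    x = df.loc[eligible, gates.x_feature].to_numpy()
    y = df.loc[eligible, gates.y_feature].to_numpy()
    labels.loc[eligible] = gates.classify(x, y)
    qc = {
        "n_total": int(len(df)),
        "n_eligible": int(eligible.sum()),
        "n_invalid_xy": int((labels[eligible] == "unassigned").sum()),
    }
    return labels, qc


# ---------------------------------------------------------------------------
# Upstream gates: singlets, focus, DNA content, mitosis, apoptosis
# ---------------------------------------------------------------------------


def _require_columns(table: FeatureTable, cols: Sequence[str], op: str) -> None:
    missing = [c for c in cols if c not in table.df.columns]
    if missing:
        raise GolgiqError(f"{op}: feature table lacks columns {missing}")


def gate_singlets_focused(table: FeatureTable, config: GateConfig) -> pd.DataFrame:
    """Singlet and focus flags from BF area, aspect ratio and gradient RMS."""
    _require_columns(
        table, ["bf_object_area", "bf_aspect_ratio", "bf_gradient_rms"], "gate_singlets_focused"
    )
    df = table.df
    s = config.singlet
    singlet = (
        (df["bf_object_area"] >= s.area_min_um2)
        & (df["bf_object_area"] <= s.area_max_um2)
        & (df["bf_aspect_ratio"] >= s.aspect_ratio_min)
    )
    focused = df["bf_gradient_rms"] >= config.focus.gradient_rms_min
    return pd.DataFrame(
        {"singlet": singlet.fillna(False), "focused": focused.fillna(False)}, index=df.index
    )


def gate_dna_content(table: FeatureTable, config: GateConfig | None = None) -> pd.Series:
    """Cell-cycle labels from the DNA total-intensity histogram.

    The G1 (2N) reference is the highest peak of a smoothed histogram
    (overridable via ``dna_content.g1_reference`` for populations where
    mitotic arrest makes the 4N peak modal).  Windows: G1 within
    [0.75, 1.25] x mode, G2M within [1.7, 2.3] x mode, between → S/
    indeterminate, outside → excluded (sub-G1 debris or aggregates).
    """
    config = config or GateConfig()
    _require_columns(table, ["dna_total_intensity"], "gate_dna_content")
    values = table.df["dna_total_intensity"]
    finite = values.dropna()
    if len(finite) < 50:
        raise GolgiqError(
            "gate_dna_content needs >= 50 cells with valid DNA intensity; "
            "set dna_content.g1_reference manually for small samples"
        )
    dc = config.dna_content
    if dc.g1_reference is not None:
        mode = float(dc.g1_reference)
    else:
        arr = finite.to_numpy()
        if arr.max() == arr.min():
            mode = float(arr[0])
        else:
            hi = float(np.quantile(arr, 0.995)) * 1.05
            hist, edges = np.histogram(arr, bins=256, range=(0, hi))
            smooth = ndimage.gaussian_filter1d(hist.astype(float), 2.0)
            if smooth.max() <= 0:
                raise GolgiqError(
                    "gate_dna_content: no detectable DNA-intensity peak; "
                    "set dna_content.g1_reference manually"
                )
            peak = int(np.argmax(smooth))
            mode = float(0.5 * (edges[peak] + edges[peak + 1]))
    g1_lo, g1_hi = dc.g1_window[0] * mode, dc.g1_window[1] * mode
    g2_lo, g2_hi = dc.g2m_window[0] * mode, dc.g2m_window[1] * mode
    labels = pd.Series("excluded", index=table.df.index, dtype=object, name="cycle")
    v = values
    labels[(v >= g1_lo) & (v <= g1_hi)] = "G1"
    labels[(v > g1_hi) & (v < g2_lo)] = "S/indeterminate"
    labels[(v >= g2_lo) & (v <= g2_hi)] = "G2M"
    labels[v.isna()] = "excluded"
    return labels


def _dna_component_stats(cell: CellRecord, min_size: int = 5) -> tuple[int, float]:
    """(significant component count, centroid separation of two largest, μm)."""
    mask = object_mask(cell.channels["DNA"], "DNA", keep="all")
    if mask.is_empty:
        return 0, 0.0
    labels_arr, n = ndimage.label(mask.raster, structure=STRUCT8)
    if n == 0:
        return 0, 0.0
    sizes = np.bincount(labels_arr.ravel())
    sizes[0] = 0
    significant = np.flatnonzero(sizes >= min_size)
    if significant.size == 0:
        significant = np.array([int(np.argmax(sizes))])
    if significant.size < 2:
        return int(significant.size), 0.0
    top2 = significant[np.argsort(sizes[significant])[-2:]]
    c1, c2 = ndimage.center_of_mass(mask.raster, labels_arr, top2)
    dist_px = math.hypot(c1[0] - c2[0], c1[1] - c2[1])
    return int(significant.size), dist_px * cell.pixel_size


def classify_mitotic(
    cells: Sequence[CellRecord],
    table: FeatureTable,
    cycle: pd.Series,
    config: GateConfig,
) -> pd.Series:
    """Mitotic sub-phase labels for G2M cells.

    Rule cascade: DNA bright-detail intensity below threshold → 'none'
    (interphase G2, smooth chromatin); otherwise two separated nuclear
    masses → anaphase (far) or telophase (near); a single condensed mass
    with small Threshold-50 DNA area → metaphase; remainder → prophase.
    """
    r = config.masks.bright_detail_radius_px
    bdi_col = f"dna_bdi_r{r}"
    _require_columns(table, [bdi_col, "dna_t50_area"], "classify_mitotic")
    by_id = {c.cell_id: c for c in cells}
    missing = [cid for cid in table.df.index if cid not in by_id]
    if missing:
        raise GolgiqError(f"classify_mitotic: missing cell images for {missing[:3]}...")
    mc = config.mitotic
    labels = pd.Series("none", index=table.df.index, dtype=object, name="mitotic")
    for cid in table.df.index[cycle.reindex(table.df.index) == "G2M"]:
        bdi = table.df.at[cid, bdi_col]
        if not np.isfinite(bdi) or bdi < mc.bright_detail_min_au:
            continue
        ncomp, sep_um = _dna_component_stats(by_id[cid])
        if ncomp >= 2:
            labels.at[cid] = "anaphase" if sep_um > mc.anaphase_min_separation_um else "telophase"
        elif table.df.at[cid, "dna_t50_area"] < mc.metaphase_t50_area_max_um2:
            labels.at[cid] = "metaphase"
        else:
            labels.at[cid] = "prophase"
    return labels


def gate_apoptotic(table: FeatureTable, config: GateConfig) -> pd.Series:
    """Apoptosis flags: BF contrast >= threshold AND DNA T50 area <= threshold."""
    _require_columns(table, ["bf_contrast", "dna_t50_area"], "gate_apoptotic")
    ap = config.apoptosis
    df = table.df
    flags = (df["bf_contrast"] >= ap.bf_contrast_min) & (df["dna_t50_area"] <= ap.dna_t50_area_max_um2)
    return flags.fillna(False).rename("apoptotic")


# ---------------------------------------------------------------------------
# Full hierarchy
# ---------------------------------------------------------------------------


@dataclass
class GatingResult:
    """Per-cell outcome of the full gating hierarchy plus QC tallies.

    ``df`` columns: singlet, focused, cycle, mitotic, apoptotic, golgi.
    Golgi labels are assigned only to singlet AND focused cells; mitotic
    labels only within G2M.
    """

    df: pd.DataFrame
    qc: dict[str, int] = field(default_factory=dict)

    @property
    def eligible(self) -> pd.Series:
        return self.df["singlet"] & self.df["focused"]


def run_gating(
    cells: Sequence[CellRecord],
    table: FeatureTable,
    config: GateConfig,
) -> GatingResult:
    """Run the full hierarchy on a feature table (and its cell images)."""
    flags = gate_singlets_focused(table, config)
    eligible = flags["singlet"] & flags["focused"]

    cycle = pd.Series("excluded", index=table.df.index, dtype=object, name="cycle")
    eligible_ids = table.df.index[eligible]
    if len(eligible_ids) >= 50:
        sub_table = FeatureTable(table.df.loc[eligible_ids], table.provenance)
        cycle.loc[eligible_ids] = gate_dna_content(sub_table, config)
        mitotic = classify_mitotic(cells, table, cycle, config)
    else:
        mitotic = pd.Series("none", index=table.df.index, dtype=object, name="mitotic")

    apoptotic = gate_apoptotic(table, config) & eligible
    gates = GolgiGates.from_config(config.golgi_gates)
    golgi, qc = classify_golgi(table, gates, eligible)

    df = pd.DataFrame(
        {
            "singlet": flags["singlet"],
            "focused": flags["focused"],
            "cycle": cycle,
            "mitotic": mitotic,
            "apoptotic": apoptotic,
            "golgi": golgi,
        },
        index=table.df.index,
    )
    return GatingResult(df, qc)


# ---------------------------------------------------------------------------
# Calibration from labeled exemplars
# ---------------------------------------------------------------------------

_HEALTHY_NUCLEI = ("interphase_g1", "interphase_g2")


def calibrate_gate_config(
    table: FeatureTable,
    truth: pd.DataFrame,
    base: GateConfig | None = None,
) -> GateConfig:
    """Calibrate every gate threshold from a labeled exemplar population.

    ``truth`` is the ground-truth table of the synthetic generator
    (columns golgi_class, nucleus_class, doublet, out_of_focus).
    Thresholds separating two reference classes sit at variance-weighted
    midpoints; one-sided gates (singlet area window, focus) are set from
    robust quantiles of the clean singlet distribution.  Returns a new
    :class:`GateConfig`; sections without calibration data keep the
    ``base`` values.
    """
    import dataclasses as _dc

    cfg = base or GateConfig()
    truth = truth.loc[truth.index.intersection(table.df.index)]
    df = table.df.loc[truth.index]
    clean = (~truth["doublet"]) & (~truth["out_of_focus"])

    def stats(series: pd.Series) -> tuple[float, float]:
        s = series.dropna()
        return float(s.mean()), float(s.std(ddof=1))

    # Singlet gate: window around the clean singlet BF-area distribution;
    # doublets sit near 2x the median area and at low aspect ratio.
    area = df.loc[clean, "bf_object_area"].dropna()
    aspect = df.loc[clean, "bf_aspect_ratio"].dropna()
    singlet = _dc.replace(
        cfg.singlet,
        area_min_um2=float(0.5 * area.median()),
        area_max_um2=float(1.5 * area.median()),
        aspect_ratio_min=float(max(0.5, aspect.quantile(0.005) - 0.08)),
    )

    # Focus gate: in-focus gradient RMS is tightly distributed; defocus
    # washes out cell texture but not the shot-noise gradient floor, which
    # sits near half the in-focus value — the cut goes just above it.
    grms = df.loc[clean, "bf_gradient_rms"].dropna()
    focus = _dc.replace(cfg.focus, gradient_rms_min=float(0.72 * grms.median()))

    healthy = clean & truth["nucleus_class"].isin(_HEALTHY_NUCLEI)
    apo = clean & (truth["nucleus_class"] == "apoptotic")

    r = cfg.masks.bright_detail_radius_px
    bdi_col = f"dna_bdi_r{r}"
    mit = cfg.mitotic
    # Boundary between the *adjacent* classes: smooth interphase-G2
    # chromatin vs prophase (the dimmest mitotic figure on bright-detail).
    g2 = clean & (truth["nucleus_class"] == "interphase_g2")
    pro = clean & (truth["nucleus_class"] == "prophase")
    if g2.sum() >= 5 and pro.sum() >= 5:
        mit = _dc.replace(
            mit,
            bright_detail_min_au=_vw_midpoint(
                *stats(df.loc[g2, bdi_col]), *stats(df.loc[pro, bdi_col])
            ),
        )
    meta = clean & (truth["nucleus_class"] == "metaphase")
    if meta.sum() >= 5 and pro.sum() >= 5:
        mit = _dc.replace(
            mit,
            metaphase_t50_area_max_um2=_vw_midpoint(
                *stats(df.loc[meta, "dna_t50_area"]), *stats(df.loc[pro, "dna_t50_area"])
            ),
        )

    apo_cfg = cfg.apoptosis
    if apo.sum() >= 5 and healthy.sum() >= 5:
        apo_cfg = _dc.replace(
            apo_cfg,
            bf_contrast_min=_vw_midpoint(
                *stats(df.loc[healthy, "bf_contrast"]), *stats(df.loc[apo, "bf_contrast"])
            ),
            dna_t50_area_max_um2=_vw_midpoint(
                *stats(df.loc[apo, "dna_t50_area"]), *stats(df.loc[healthy, "dna_t50_area"])
            ),
        )

    sub = FeatureTable(df.loc[clean], table.provenance)
    gates = fit_golgi_gates(sub, truth.loc[clean, "golgi_class"])

    out = GateConfig(
        masks=cfg.masks,
        singlet=singlet,
        focus=focus,
        dna_content=cfg.dna_content,
        mitotic=mit,
        apoptosis=apo_cfg,
        golgi_gates=gates.to_config(),
    )
    out.validate()
    return out
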