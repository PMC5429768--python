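"""Synthetic multispectral single-cell image generator.

Renders 64x64 px three-channel (BF / Golgi marker / DNA stain) cell
tiles with known ground truth, emulating the populations an imaging
flow cytometer records:

* **Golgi morphologies** — *intact*: 2-4 overlapping blobs along a
  perinuclear arc (compact, elongated footprint); *partial*: 4-8
  discrete puncta within 1.5x the nucleus radius; *full*: tens of small
  vesicles dispersed over the whole cell footprint.  Intact Golgi thus
  shows small Threshold-60 area and a narrow intensity-weighted ellipse,
  fully fragmented Golgi a large area and a round footprint — the
  separation the downstream gates rely on.
* **Nuclear states** — interphase G1/G2 (2N vs 4N total DNA), prophase
  (speckled chromatin, high bright-detail), metaphase (condensed plate:
  low Threshold-50 area), anaphase/telophase (two separated masses),
  apoptotic (few very bright condensed blobs plus speckled bright-field
  texture).
* **Acquisition artifacts** — out-of-focus cells (extra Gaussian blur)
  and cell doublets (second cell ~1.5 radii away in the same tile).

Noise model: Poisson shot noise (``signal = Poisson(clean*gain)/gain``)
plus Gaussian read noise and a constant camera offset, quantized to
16-bit integers.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .ifcio import CellRecord, ValidationError

__all__ = [
    "GolgiClass",
    "NucleusClass",
    "NoiseModel",
    "Geometry",
    "SynthCellSpec",
    "PopulationPreset",
    "render_cell",
    "sample_population",
    "get_preset",
    "preset_names",
]


class GolgiClass(enum.Enum):
    INTACT = "intact"
    PARTIAL = "partial"
    FULL = "full"


class NucleusClass(enum.Enum):
    INTERPHASE_G1 = "interphase_g1"
    INTERPHASE_G2 = "interphase_g2"
    PROPHASE = "prophase"
    METAPHASE = "metaphase"
    ANAPHASE = "anaphase"
    TELOPHASE = "telophase"
    APOPTOTIC = "apoptotic"


#: 4N (post-replication) nuclear states.
_4N = {
    NucleusClass.INTERPHASE_G2,
    NucleusClass.PROPHASE,
    NucleusClass.METAPHASE,
    NucleusClass.ANAPHASE,
    NucleusClass.TELOPHASE,
}

# Total clean-signal budgets (au) before noise; DNA scales with ploidy so
# that 4N states integrate to ~2x the 2N mean.
_DNA_TOTAL_2N = 40_000.0
_DNA_TOTAL_APOPTOTIC = 28_000.0  # sub-G1: partial DNA loss, condensed
_GOLGI_TOTAL = 18_000.0
_BF_AMPLITUDE = 300.0


@dataclass(frozen=True)
class NoiseModel:
    """Poisson + Gaussian camera model: offset, read noise SD, photon gain."""

    offset: float = 5.0
    read_sd: float = 2.0
    gain: float = 0.25

    def __post_init__(self) -> None:
        if self.read_sd < 0 or self.offset < 0 or self.gain <= 0:
            raise ValidationError("noise parameters must be non-negative (gain > 0)")


@dataclass(frozen=True)
class Geometry:
    """Tile geometry: canvas (px), pixel size (μm), cell/nucleus radii (μm)."""

    canvas: int = 64
    pixel_size: float = 0.5
    cell_radius_um: float = 7.5
    nucleus_radius_um: float = 4.5

    def __post_init__(self) -> None:
        if self.canvas < 48:
            raise ValidationError(f"canvas must be >= 48 px, got {self.canvas}")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if self.cell_radius_px + 4 > self.canvas / 2:
            raise ValidationError(
                f"cell radius {self.cell_radius_um} μm does not fit a "
                f"{self.canvas}-px canvas with a 4-px margin"
            )
        if self.nucleus_radius_um >= self.cell_radius_um:
            raise ValidationError("nucleus radius must be smaller than cell radius")

    @property
    def cell_radius_px(self) -> float:
        return self.cell_radius_um / self.pixel_size

    @property
    def nucleus_radius_px(self) -> float:
        return self.nucleus_radius_um / self.pixel_size


@dataclass(frozen=True)
class SynthCellSpec:
    """Generative parameters for one synthetic cell."""

    golgi_class: GolgiClass
    nucleus_class: NucleusClass
    focus_sigma: float = 0.0  # extra blur (px); 0 = in focus
    is_doublet: bool = False
    noise: NoiseModel = field(default_factory=NoiseModel)
    geometry: Geometry = field(default_factory=Geometry)
    # Optional per-cell morphology overrides (None → sampled from class ranges)
    golgi_n_puncta: int | None = None
    golgi_dispersion_um: float | None = None
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        if self.focus_sigma < 0:
            raise ValidationError("focus_sigma must be >= 0")
        if self.golgi_dispersion_um is not None:
            max_disp = self.geometry.cell_radius_um
            if not (0 < self.golgi_dispersion_um <= max_disp):
                raise ValidationError(
                    f"golgi_dispersion_um must be in (0, {max_disp}] μm"
                )


# ---------------------------------------------------------------------------
# Rendering primitives
# ---------------------------------------------------------------------------


def _grids(canvas: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[0:canvas, 0:canvas].astype(float)
    return yy, xx


def _gaussian(yy, xx, cy, cx, sigma, amp=1.0):
    return amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))


def _soft_disk(yy, xx, cy, cx, radius, edge=1.2):
    r = np.hypot(yy - cy, xx - cx)
    return 1.0 / (1.0 + np.exp((r - radius) / edge))


def _normalize_total(img: np.ndarray, total: float) -> np.ndarray:
    s = img.sum()
    return img * (total / s) if s > 0 else img


def _granule_cluster(yy, xx, cy, cx, n, spread, sigma, rng):
    """n Gaussian granules scattered uniformly within `spread` px of (cy,cx)."""
    img = np.zeros_like(yy)
    for _ in range(n):
        r = spread * math.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * math.pi)
        amp = rng.uniform(0.6, 1.4)
        img += _gaussian(yy, xx, cy + r * math.sin(th), cx + r * math.cos(th), sigma, amp)
    return img


# ---------------------------------------------------------------------------
# Channel renderers (clean, float, before blur/noise)
# ---------------------------------------------------------------------------


def _render_golgi(spec: SynthCellSpec, rng, yy, xx, cy, cx, scale=1.0) -> np.ndarray:
    geo = spec.geometry
    nuc_r = geo.nucleus_radius_px * scale
    cell_r = geo.cell_radius_px * scale
    img = np.zeros_like(yy)

    if spec.golgi_class is GolgiClass.INTACT:
        n = spec.golgi_n_puncta or int(rng.integers(2, 5))
        theta0 = rng.uniform(0, 2 * math.pi)
        span = rng.uniform(0.5, 0.75)  # rad (~29-43 deg)
        arc_r = nuc_r + 1.5
        angles = theta0 + np.linspace(-span / 2, span / 2, n) + rng.normal(0, 0.05, n)
        for th in angles:
            r = arc_r + rng.normal(0, 0.25)
            sigma = rng.uniform(0.85, 1.1)
            img += _gaussian(yy, xx, cy + r * math.sin(th), cx + r * math.cos(th), sigma)
    elif spec.golgi_class is GolgiClass.PARTIAL:
        n = spec.golgi_n_puncta or int(rng.integers(4, 9))
        if spec.golgi_dispersion_um is not None:
            disp = spec.golgi_dispersion_um / geo.pixel_size * scale
        else:
            disp = rng.uniform(0.65, 0.85) * nuc_r  # <= 1.5x nucleus radius
        # fragment size trades off against count (conserved Golgi material),
        # which keeps the total stained footprint comparatively stable
        sigma_base = rng.uniform(1.25, 1.4) * (6.0 / n) ** 0.3
        theta0 = rng.uniform(0, 2 * math.pi)
        for i in range(n):
            # stratified angles: puncta ring the nucleus rather than clump
            th = theta0 + 2 * math.pi * (i + rng.uniform(-0.3, 0.3)) / n
            r = disp * math.sqrt(rng.uniform(0.35, 1.0))
            sigma = sigma_base * rng.uniform(0.9, 1.1)
            img += _gaussian(yy, xx, cy + r * math.sin(th), cx + r * math.cos(th), sigma)
    else:  # FULL: vesicles over the whole cell footprint
        n = spec.golgi_n_puncta or int(rng.integers(25, 61))
        if spec.golgi_dispersion_um is not None:
            disp = spec.golgi_dispersion_um / geo.pixel_size * scale
        else:
            disp = rng.uniform(0.85, 0.98) * cell_r
        for _ in range(n):
            r = disp * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            sigma = rng.uniform(0.7, 0.95)
            img += _gaussian(yy, xx, cy + r * math.sin(th), cx + r * math.cos(th), sigma)

    total = _GOLGI_TOTAL * scale**2 * rng.lognormal(0.0, 0.15)
    return _normalize_total(img, total)


def _render_dna(spec: SynthCellSpec, rng, yy, xx, cy, cx, scale=1.0) -> np.ndarray:
    geo = spec.geometry
    nuc_r = geo.nucleus_radius_px * scale
    nc = spec.nucleus_class
    cy = cy + rng.normal(0, 1.0)
    cx = cx + rng.normal(0, 1.0)

    if nc in (NucleusClass.INTERPHASE_G1, NucleusClass.INTERPHASE_G2):
        img = _soft_disk(yy, xx, cy, cx, nuc_r, edge=1.5)
    elif nc is NucleusClass.PROPHASE:
        # condensing chromatin: interphase-sized disk plus bright granules
        # (keeps Threshold-50 area near interphase, unlike the metaphase plate)
        disk_part = _normalize_total(_soft_disk(yy, xx, cy, cx, nuc_r, edge=1.5), 1.0)
        speckle = _normalize_total(
            _granule_cluster(yy, xx, cy, cx, 12, 0.9 * nuc_r, 1.3, rng), 1.0
        )
        img = 0.65 * disk_part + 0.35 * speckle
    elif nc is NucleusClass.METAPHASE:
        # condensed plate: thin rotated bar, low Threshold-50 area
        theta = rng.uniform(0, math.pi)
        u = (yy - cy) * math.cos(theta) + (xx - cx) * math.sin(theta)
        v = -(yy - cy) * math.sin(theta) + (xx - cx) * math.cos(theta)
        half_len = 1.2 * nuc_r
        half_wid = 0.28 * nuc_r
        img = 1.0 / (1.0 + np.exp((np.abs(u) - half_len) / 0.8))
        img *= 1.0 / (1.0 + np.exp((np.abs(v) - half_wid) / 0.6))
    elif nc in (NucleusClass.ANAPHASE, NucleusClass.TELOPHASE):
        if nc is NucleusClass.ANAPHASE:
            half_sep, spread, sigma, n_gran = 7.0, 2.2, 0.9, 6
        else:  # telophase: masses closer together, larger and dimmer
            half_sep, spread, sigma, n_gran = 4.5, 3.2, 1.1, 8
        theta = rng.uniform(0, 2 * math.pi)
        dy, dx = half_sep * math.sin(theta), half_sep * math.cos(theta)
        img = _granule_cluster(yy, xx, cy + dy, cx + dx, n_gran, spread, sigma, rng)
        img += _granule_cluster(yy, xx, cy - dy, cx - dx, n_gran, spread, sigma, rng)
    else:  # APOPTOTIC: few very bright condensed blobs
        n = int(rng.integers(2, 5))
        img = _granule_cluster(yy, xx, cy, cx, n, 3.5, 1.3, rng)

    if nc is NucleusClass.APOPTOTIC:
        total = _DNA_TOTAL_APOPTOTIC
    else:
        total = _DNA_TOTAL_2N * (2.0 if nc in _4N else 1.0)
    total *= scale**2 * rng.lognormal(0.0, 0.08)
    return _normalize_total(img, total)


def _render_bf(spec: SynthCellSpec, rng, yy, xx, cy, cx, scale=1.0) -> np.ndarray:
    geo = spec.geometry
    cell_r = geo.cell_radius_px * scale
    disk_ = _soft_disk(yy, xx, cy, cx, cell_r, edge=1.2)
    if spec.nucleus_class is NucleusClass.APOPTOTIC:
        # membrane blebbing / condensation: sharp, high-variance speckle
        amp, corr = 0.45, 0.8
    else:
        # smooth intracellular texture; defocus washes it out, which is
        # what the gradient-RMS focus gate detects
        amp, corr = 0.30, 1.6
    field_ = gaussian_filter(rng.standard_normal(yy.shape), corr)
    field_ /= max(field_.std(), 1e-9)
    img = _BF_AMPLITUDE * disk_ * (1.0 + amp * np.clip(field_, -2.0, 2.0))
    return img


def _render_clean(spec: SynthCellSpec, rng, yy, xx, cy, cx, scale=1.0):
    bf = _render_bf(spec, rng, yy, xx, cy, cx, scale)
    golgi = _render_golgi(spec, rng, yy, xx, cy, cx, scale)
    dna = _render_dna(spec, rng, yy, xx, cy, cx, scale)
    return bf, golgi, dna


# ---------------------------------------------------------------------------
# Cell and population generation
# ---------------------------------------------------------------------------


def render_cell(spec: SynthCellSpec, rng_seed: int) -> CellRecord:
    """Render one synthetic cell; deterministic for fixed (spec, seed)."""
    rng = np.random.default_rng(rng_seed)
    geo = spec.geometry
    yy, xx = _grids(geo.canvas)
    half = geo.canvas / 2.0

    if spec.is_doublet:
        # two cells ~1.5 radii apart, second at 0.8-1.2x size
        sep = rng.uniform(1.4, 1.6) * geo.cell_radius_px
        theta = rng.uniform(0, 2 * math.pi)
        dy, dx = (sep / 2) * math.sin(theta), (sep / 2) * math.cos(theta)
        scale2 = rng.uniform(0.8, 1.2)
        bf1, g1, d1 = _render_clean(spec, rng, yy, xx, half + dy, half + dx, 1.0)
        bf2, g2, d2 = _render_clean(spec, rng, yy, xx, half - dy, half - dx, scale2)
        bf, golgi, dna = bf1 + bf2, g1 + g2, d1 + d2
    else:
        cy = half + rng.uniform(-2, 2)
        cx = half + rng.uniform(-2, 2)
        bf, golgi, dna = _render_clean(spec, rng, yy, xx, cy, cx, 1.0)

    channels = {}
    for name, clean in (("BF", bf), ("GOLGI", golgi), ("DNA", dna)):
        if spec.focus_sigma > 0:
            clean = gaussian_filter(clean, spec.focus_sigma)
        nm = spec.noise
        noisy = rng.poisson(np.maximum(clean, 0.0) * nm.gain) / nm.gain
        noisy = noisy + rng.normal(0.0, nm.read_sd, clean.shape) + nm.offset
        channels[name] = np.clip(np.round(noisy), 0, 65535).astype(np.uint16)

    return CellRecord(
        cell_id=spec.cell_id,
        channels=channels,
        pixel_size=geo.pixel_size,
        meta={
            "golgi_class": spec.golgi_class.value,
            "nucleus_class": spec.nucleus_class.value,
        },
    )


@dataclass(frozen=True)
class PopulationPreset:
    """Generative parameters for a labeled synthetic population."""

    name: str
    mixture: dict[tuple[GolgiClass, NucleusClass], float]
    n_default: int = 5000
    doublet_rate: float = 0.06
    out_of_focus_rate: float = 0.05
    geometry: Geometry = field(default_factory=Geometry)
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"preset {self.name!r}: mixture sums to {total}, not 1")
        if any(p < 0 for p in self.mixture.values()):
            raise ValidationError(f"preset {self.name!r}: negative mixture probability")
        for rate, label in ((self.doublet_rate, "doublet_rate"),
                            (self.out_of_focus_rate, "out_of_focus_rate")):
            if not (0 <= rate <= 1):
                raise ValidationError(f"preset {self.name!r}: {label} must be in [0,1]")

    def golgi_marginal(self) -> dict[GolgiClass, float]:
        out = {g: 0.0 for g in GolgiClass}
        for (g, _), p in self.mixture.items():
            out[g] += p
        return out

    def nucleus_marginal(self) -> dict[NucleusClass, float]:
        out = {nc: 0.0 for nc in NucleusClass}
        for (_, nc), p in self.mixture.items():
            out[nc] += p
        return out


def sample_population(
    preset: PopulationPreset, n: int, seed: int
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Draw n cells from a preset; returns (cells, ground-truth table).

    Class counts are multinomial draws from the preset mixture; doublet
    and out-of-focus flags are independent Bernoulli draws at the preset
    rates; per-cell morphology parameters come from the class ranges.
    Ground truth covers every cell exactly once (index = cell_id, columns
    golgi_class, nucleus_class, doublet, out_of_focus).
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    combos = sorted(preset.mixture.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value))
    probs = np.array([p for _, p in combos])
    counts = rng.multinomial(n, probs / probs.sum())
    assignments: list[tuple[GolgiClass, NucleusClass]] = []
    for (combo, _), c in zip(combos, counts):
        assignments.extend([combo] * c)
    order = rng.permutation(n)

    cells: list[CellRecord] = []
    truth_rows = []
    for i in range(n):
        golgi_cls, nuc_cls = assignments[order[i]]
        is_doublet = bool(rng.random() < preset.doublet_rate)
        oof = bool(rng.random() < preset.out_of_focus_rate)
        focus_sigma = float(rng.uniform(2.5, 4.0)) if oof else 0.0
        cell_id = f"{preset.name}_{i:05d}"
        spec = SynthCellSpec(
            golgi_class=golgi_cls,
            nucleus_class=nuc_cls,
            focus_sigma=focus_sigma,
            is_doublet=is_doublet,
            noise=preset.noise,
            geometry=preset.geometry,
            cell_id=cell_id,
        )
        cell_seed = int(rng.integers(0, 2**31))
        cell = render_cell(spec, cell_seed)
        cell.meta["condition"] = preset.name
        cells.append(cell)
        truth_rows.append(
            {
                "cell_id": cell_id,
                "golgi_class": golgi_cls.value,
                "nucleus_class": nuc_cls.value,
                "doublet": is_doublet,
                "out_of_focus": oof,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("cell_id")
    return cells, truth


# ---------------------------------------------------------------------------
# Presets: population mixtures matching the studied treatment conditions
# ---------------------------------------------------------------------------


def _product_mixture(
    golgi: dict[GolgiClass, float], nucleus: dict[NucleusClass, float]
) -> dict[tuple[GolgiClass, NucleusClass], float]:
    return {(g, nc): pg * pn for g, pg in golgi.items() for nc, pn in nucleus.items()}


_G = GolgiClass
_N = NucleusClass

# Interphase-dominated cycling culture.
_NUC_CYCLING = {
    _N.INTERPHASE_G1: 0.60, _N.INTERPHASE_G2: 0.32, _N.PROPHASE: 0.02,
    _N.METAPHASE: 0.02, _N.ANAPHASE: 0.01, _N.TELOPHASE: 0.01, _N.APOPTOTIC: 0.02,
}


def _build_presets() -> dict[str, PopulationPreset]:
    presets: dict[str, PopulationPreset] = {}

    presets["untreated"] = PopulationPreset(
        "untreated",
        _product_mixture({_G.INTACT: 0.80, _G.PARTIAL: 0.17, _G.FULL: 0.03}, _NUC_CYCLING),
    )
    presets["wi38"] = PopulationPreset(
        "wi38",
        _product_mixture({_G.INTACT: 0.82, _G.PARTIAL: 0.15, _G.FULL: 0.03}, _NUC_CYCLING),
    )
    presets["noc_4h"] = PopulationPreset(
        "noc_4h",
        _product_mixture(
            {_G.INTACT: 0.25, _G.PARTIAL: 0.60, _G.FULL: 0.15},
            {_N.INTERPHASE_G1: 0.38, _N.INTERPHASE_G2: 0.40, _N.PROPHASE: 0.09,
             _N.METAPHASE: 0.09, _N.ANAPHASE: 0.01, _N.TELOPHASE: 0.01, _N.APOPTOTIC: 0.02},
        ),
    )
    presets["noc_16h"] = PopulationPreset(
        "noc_16h",
        _product_mixture(
            {_G.INTACT: 0.10, _G.PARTIAL: 0.25, _G.FULL: 0.65},
            {_N.INTERPHASE_G1: 0.12, _N.INTERPHASE_G2: 0.30, _N.PROPHASE: 0.15,
             _N.METAPHASE: 0.38, _N.ANAPHASE: 0.01, _N.TELOPHASE: 0.01, _N.APOPTOTIC: 0.03},
        ),
    )
    presets["bfa_60min"] = PopulationPreset(
        "bfa_60min",
        _product_mixture({_G.INTACT: 0.20, _G.PARTIAL: 0.75, _G.FULL: 0.05}, _NUC_CYCLING),
    )
    presets["tnf_chx_6h"] = PopulationPreset(
        "tnf_chx_6h",
        _product_mixture(
            {_G.INTACT: 0.35, _G.PARTIAL: 0.60, _G.FULL: 0.05},
            {_N.APOPTOTIC: 0.75, _N.INTERPHASE_G1: 0.15, _N.INTERPHASE_G2: 0.08,
             _N.PROPHASE: 0.005, _N.METAPHASE: 0.005, _N.ANAPHASE: 0.005, _N.TELOPHASE: 0.005},
        ),
    )

    # Mitotic-synchronized release: Golgi state follows the cell-cycle phase
    # (fragmenting through prophase-anaphase, reassembling at telophase).
    nuc_marginal = {
        _N.INTERPHASE_G1: 0.10, _N.INTERPHASE_G2: 0.35, _N.PROPHASE: 0.15,
        _N.METAPHASE: 0.20, _N.ANAPHASE: 0.08, _N.TELOPHASE: 0.10, _N.APOPTOTIC: 0.02,
    }
    golgi_given_nuc = {
        _N.INTERPHASE_G1: (0.85, 0.13, 0.02),
        _N.INTERPHASE_G2: (0.35, 0.55, 0.10),
        _N.PROPHASE: (0.15, 0.60, 0.25),
        _N.METAPHASE: (0.05, 0.15, 0.80),
        _N.ANAPHASE: (0.05, 0.20, 0.75),
        _N.TELOPHASE: (0.30, 0.45, 0.25),
        _N.APOPTOTIC: (0.35, 0.60, 0.05),
    }
    mixture = {
        (g, nc): nuc_marginal[nc] * cond[i]
        for nc, cond in golgi_given_nuc.items()
        for i, g in enumerate((_G.INTACT, _G.PARTIAL, _G.FULL))
    }
    presets["thymidine_release_9h"] = PopulationPreset("thymidine_release_9h", mixture)

    # Balanced labeled exemplars for gate calibration (a synthetic stand-in
    # for manually classified reference cells); clean singlets, in focus,
    # with enough mitotic and apoptotic nuclei to calibrate every gate.
    presets["exemplars"] = PopulationPreset(
        "exemplars",
        _product_mixture(
            {_G.INTACT: 1 / 3, _G.PARTIAL: 1 / 3, _G.FULL: 1 / 3},
            {_N.INTERPHASE_G1: 0.40, _N.INTERPHASE_G2: 0.15, _N.PROPHASE: 0.08,
             _N.METAPHASE: 0.07, _N.ANAPHASE: 0.05, _N.TELOPHASE: 0.05, _N.APOPTOTIC: 0.20},
        ),
        n_default=300,
        doublet_rate=0.0,
        out_of_focus_rate=0.0,
    )
    return presets


_PRESETS = _build_presets()


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def get_preset(name: str) -> PopulationPreset:
    """Return a named population preset.

    Available: untreated, noc_4h, noc_16h, thymidine_release_9h,
    bfa_60min, tnf_chx_6h, wi38, exemplars.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
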