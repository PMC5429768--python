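"""Data model and file I/O for the Golgi-fragmentation IFC pipeline.

The atomic analysis unit is a :class:`CellRecord`: three aligned channel
rasters (bright-field ``BF``, Golgi-marker fluorescence ``GOLGI``, DNA
stain ``DNA``) for one cell, plus pixel size and free-form metadata.
Samples are stored on disk as one multi-page TIFF per cell (pages in the
fixed order BF, GOLGI, DNA; 16-bit unsigned) plus a CSV manifest;
per-cell features travel in a :class:`FeatureTable` (CSV + provenance
sidecar); gate thresholds and regions are a :class:`GateConfig`
(JSON canonical, YAML accepted).

Conventions: rasters are row-major with 0-based indices and pixel
centers at integer coordinates; all lengths are reported in μm via
``pixel_size``; intensities are dimensionless "au".
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("golgiq")

__all__ = [
    "CHANNELS",
    "GolgiqError",
    "FormatError",
    "ValidationError",
    "CellRecord",
    "SampleManifest",
    "FeatureTable",
    "GateConfig",
    "MaskParams",
    "SingletGateConfig",
    "FocusGateConfig",
    "DnaContentConfig",
    "MitoticConfig",
    "ApoptosisConfig",
    "GolgiRegionConfig",
    "read_sample",
    "write_sample",
    "write_feature_table",
    "read_feature_table",
    "load_gate_config",
    "save_gate_config",
]

#: Fixed channel order, matching TIFF page order.
CHANNELS = ("BF", "GOLGI", "DNA")

SCHEMA_VERSION = 1


class GolgiqError(Exception):
    """Base class for package errors."""


class FormatError(GolgiqError):
    """Malformed input file (wrong page count, mismatched shapes, ...)."""


class ValidationError(GolgiqError):
    """Invalid configuration or invariant violation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CellRecord:
    """One cell's aligned channel rasters plus metadata.

    ``channels`` maps channel name ("BF", "GOLGI", "DNA") to a 2-D
    non-negative intensity raster; all rasters share one shape.
    ``pixel_size`` is μm per pixel (square pixels).
    """

    cell_id: str
    channels: dict[str, np.ndarray]
    pixel_size: float
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.cell_id:
            raise ValidationError("cell_id must be non-empty")
        if self.pixel_size <= 0 or not np.isfinite(self.pixel_size):
            raise ValidationError(f"pixel_size must be positive, got {self.pixel_size}")
        shapes = set()
        for name in CHANNELS:
            if name not in self.channels:
                raise ValidationError(f"cell {self.cell_id!r}: missing channel {name}")
            arr = np.asarray(self.channels[name])
            if arr.ndim != 2:
                raise ValidationError(f"cell {self.cell_id!r}: channel {name} is not 2-D")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValidationError(
                    f"cell {self.cell_id!r}: channel {name} has negative or non-finite values"
                )
            self.channels[name] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise FormatError(f"cell {self.cell_id!r}: channel rasters differ in shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels["BF"].shape  # type: ignore[return-value]


@dataclass
class SampleManifest:
    """An ordered sample: cell records with condition/replicate labels."""

    sample_id: str
    cells: list[CellRecord]
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"sample {self.sample_id!r}: duplicate cell_ids")

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]


class FeatureTable:
    """Cells × named per-cell features, with per-feature provenance.

    ``df`` is indexed by cell_id; each column has an entry in
    ``provenance`` recording the channel, mask recipe, parameters and
    unit that produced it.  Invalid (flagged) values are stored as NaN
    rather than dropped.
    """

    def __init__(self, df: pd.DataFrame, provenance: Mapping[str, Mapping[str, Any]]):
        if df.index.name != "cell_id":
            df = df.copy()
            df.index.name = "cell_id"
        if df.index.has_duplicates:
            raise ValidationError("FeatureTable: duplicate cell_ids")
        missing = [c for c in df.columns if c not in provenance]
        if missing:
            raise ValidationError(f"FeatureTable: columns without provenance: {missing}")
        self.df = df
        self.provenance = {k: dict(v) for k, v in provenance.items() if k in df.columns}

    @property
    def cell_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    def unit(self, feature: str) -> str:
        return str(self.provenance[feature].get("unit", "au"))

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, feature: str) -> pd.Series:
        return self.df[feature]


# ---------------------------------------------------------------------------
# Gate configuration
# ---------------------------------------------------------------------------


def _check_keys(d: Mapping[str, Any], allowed: Sequence[str], where: str) -> None:
    unknown = sorted(set(d) - set(allowed))
    if unknown:
        raise ValidationError(f"unknown keys in {where}: {unknown}")


@dataclass
class MaskParams:
    """Mask parameters shared by the feature panel."""

    golgi_threshold_pct: float = 60.0
    dna_threshold_pct: float = 50.0
    bright_detail_radius_px: int = 3
    threshold_mode: str = "pixel_count"  # or "intensity"

    def validate(self) -> None:
        for v, name in ((self.golgi_threshold_pct, "golgi_threshold_pct"),
                        (self.dna_threshold_pct, "dna_threshold_pct")):
            if not (0 < v <= 100):
                raise ValidationError(f"masks.{name} must be in (0,100], got {v}")
        if self.bright_detail_radius_px < 1:
            raise ValidationError("masks.bright_detail_radius_px must be >= 1")
        if self.threshold_mode not in ("pixel_count", "intensity"):
            raise ValidationError(f"masks.threshold_mode: {self.threshold_mode!r}")


@dataclass
class SingletGateConfig:
    """Single-cell gate on BF object area (μm²) and aspect ratio.

    Defaults calibrated on the synthetic exemplar population: doublets
    sit near twice the singlet area and at aspect ratio ~0.55.
    """

    area_min_um2: float = 86.0
    area_max_um2: float = 256.0
    aspect_ratio_min: float = 0.79


@dataclass
class FocusGateConfig:
    """Focus gate on bright-field gradient RMS (au).

    Default calibrated on synthetic exemplars (in-focus median ~440 au;
    defocus collapses the value toward the shot-noise floor ~230 au).
    """

    gradient_rms_min: float = 319.0


@dataclass
class DnaContentConfig:
    """DNA-content windows relative to the G1 (2N) mode."""

    g1_window: tuple[float, float] = (0.75, 1.25)
    g2m_window: tuple[float, float] = (1.7, 2.3)
    g1_reference: float | None = None  # override when the 2N peak is not the modal peak

    def validate(self) -> None:
        lo1, hi1 = self.g1_window
        lo2, hi2 = self.g2m_window
        if not (0 < lo1 < hi1 <= lo2 < hi2):
            raise ValidationError("dna_content windows must satisfy 0 < g1_lo < g1_hi <= g2m_lo < g2m_hi")


@dataclass
class MitoticConfig:
    """Mitotic sub-phase thresholds on the DNA channel.

    Defaults calibrated on synthetic exemplars: smooth interphase
    chromatin scores ~7e3 au bright-detail vs >2e4 for mitotic figures;
    the condensed metaphase plate halves the Threshold-50 DNA area.
    """

    bright_detail_min_au: float = 12200.0
    metaphase_t50_area_max_um2: float = 16.2
    anaphase_min_separation_um: float = 5.75


@dataclass
class ApoptosisConfig:
    """Apoptosis gate: high BF contrast and condensed (small) DNA T50 area."""

    bf_contrast_min: float = 2.0
    dna_t50_area_max_um2: float = 22.0


@dataclass
class GolgiRegionConfig:
    """Serialized intact / partial / full decision regions.

    The canonical form is rectangular: ``intact_max = (x, y)`` and
    ``full_min = (x, y)`` on the plane x = Threshold-60 minor-axis
    intensity (μm), y = Threshold-60 area (μm²).  Intact is the
    closed-below corner x <= intact_max[0] and y <= intact_max[1]; full is
    the open-above corner x > full_min[0] and y > full_min[1]; partial is
    the complement, so the three regions always partition the quadrant.
    An optional polygon form (``polygons``) replaces the rectangles for
    users replicating hand-drawn gates.
    """

    x_feature: str = "golgi_t60_minor_axis_intensity"
    y_feature: str = "golgi_t60_area"
    intact_max: tuple[float, float] = (1.9, 5.9)
    full_min: tuple[float, float] = (8.8, 16.1)
    polygons: dict[str, list[list[float]]] | None = None

    def validate(self) -> None:
        if self.polygons is not None:
            labels = set(self.polygons)
            if labels != {"intact", "partial", "full"}:
                raise ValidationError(
                    f"golgi_gates.polygons must define intact/partial/full, got {sorted(labels)}"
                )
            from shapely.geometry import Polygon

            polys = {k: Polygon(v) for k, v in self.polygons.items()}
            for k, p in polys.items():
                if not p.is_valid or p.area <= 0:
                    raise ValidationError(f"golgi_gates.polygons[{k!r}] is degenerate")
            for a, b in (("intact", "partial"), ("intact", "full"), ("partial", "full")):
                if polys[a].intersection(polys[b]).area > 1e-12:
                    raise ValidationError(f"golgi_gates regions {a!r} and {b!r} overlap")
            return
        if not all(np.isfinite(self.intact_max)) or not all(np.isfinite(self.full_min)):
            raise ValidationError("golgi_gates thresholds must be finite")
        for i, axis in enumerate(("x", "y")):
            if self.intact_max[i] > self.full_min[i]:
                raise ValidationError(
                    f"golgi_gates: intact and full regions overlap on the {axis} axis "
                    f"(intact_max[{i}]={self.intact_max[i]} > full_min[{i}]={self.full_min[i]})"
                )


@dataclass
class GateConfig:
    """Every threshold and region of the gating hierarchy, serializable.

    Round-trips losslessly through JSON (canonical) or YAML.
    """

    masks: MaskParams = field(default_factory=MaskParams)
    singlet: SingletGateConfig = field(default_factory=SingletGateConfig)
    focus: FocusGateConfig = field(default_factory=FocusGateConfig)
    dna_content: DnaContentConfig = field(default_factory=DnaContentConfig)
    mitotic: MitoticConfig = field(default_factory=MitoticConfig)
    apoptosis: ApoptosisConfig = field(default_factory=ApoptosisConfig)
    golgi_gates: GolgiRegionConfig = field(default_factory=GolgiRegionConfig)
    schema_version: int = SCHEMA_VERSION

    _SECTIONS = {
        "masks": MaskParams,
        "singlet": SingletGateConfig,
        "focus": FocusGateConfig,
        "dna_content": DnaContentConfig,
        "mitotic": MitoticConfig,
        "apoptosis": ApoptosisConfig,
        "golgi_gates": GolgiRegionConfig,
    }

    def validate(self) -> None:
        self.masks.validate()
        self.dna_content.validate()
        self.golgi_gates.validate()
        for section in (self.singlet, self.focus, self.mitotic, self.apoptosis):
            for f in dataclasses.fields(section):
                v = getattr(section, f.name)
                if isinstance(v, (int, float)) and not np.isfinite(v):
                    raise ValidationError(f"{type(section).__name__}.{f.name} must be finite")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GateConfig":
        _check_keys(d, [*cls._SECTIONS, "schema_version"], "gate config")
        version = d.get("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValidationError(f"unsupported schema_version {version}")
        kwargs: dict[str, Any] = {"schema_version": version}
        for name, section_cls in cls._SECTIONS.items():
            sub = d.get(name, {})
            allowed = [f.name for f in dataclasses.fields(section_cls)]
            _check_keys(sub, allowed, name)
            coerced = {}
            for f in dataclasses.fields(section_cls):
                if f.name in sub:
                    v = sub[f.name]
                    if isinstance(v, list) and f.name != "polygons":
                        v = tuple(v)
                    coerced[f.name] = v
            kwargs[name] = section_cls(**coerced)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict[str, Any]:
        def convert(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [convert(v) for v in obj]
            return obj

        out: dict[str, Any] = {"schema_version": self.schema_version}
        for name in self._SECTIONS:
            out[name] = convert(getattr(self, name))
        return out


def load_gate_config(path: str | Path) -> GateConfig:
    """Load and validate a :class:`GateConfig` from JSON or YAML."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: gate config must be a mapping")
    return GateConfig.from_dict(data)


def save_gate_config(config: GateConfig, path: str | Path) -> None:
    config.validate()
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    else:
        path.write_text(json.dumps(config.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Sample I/O: per-cell multi-page TIFFs + manifest CSV
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ("cell_id", "tiff_path", "condition", "replicate")


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value
    unit = getattr(unit, "value", unit)
    px_per_unit = num / den
    if unit == 3:  # centimeter
        return 1e4 / px_per_unit
    if unit == 2:  # inch
        return 2.54e4 / px_per_unit
    return None


def read_sample(manifest_path: str | Path) -> SampleManifest:
    """Read a sample manifest CSV and load every cell's TIFF.

    The manifest must have columns ``cell_id, tiff_path, condition,
    replicate`` (an optional ``pixel_size_um`` column is the fallback
    when TIFF resolution tags are absent).  TIFF paths are resolved
    relative to the manifest's directory.  Cells are returned in manifest
    order.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FormatError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, dtype={"cell_id": str})
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{manifest_path}: manifest missing columns {missing}")
    base = manifest_path.parent
    cells: list[CellRecord] = []
    condition = ""
    replicate = 0
    for row in df.itertuples(index=False):
        cell_id = str(row.cell_id)
        tiff_path = base / str(row.tiff_path)
        if not tiff_path.exists():
            raise FormatError(f"cell {cell_id!r}: image file not found: {tiff_path}")
        with tifffile.TiffFile(tiff_path) as tif:
            n_pages = len(tif.pages)
            if n_pages < len(CHANNELS):
                raise FormatError(
                    f"cell {cell_id!r}: expected >= {len(CHANNELS)} TIFF pages "
                    f"(BF, GOLGI, DNA), found {n_pages}"
                )
            arrays = [tif.pages[i].asarray() for i in range(len(CHANNELS))]
            pixel_size = _pixel_size_from_tags(tif)
        if pixel_size is None:
            if "pixel_size_um" in df.columns and np.isfinite(getattr(row, "pixel_size_um", np.nan)):
                pixel_size = float(row.pixel_size_um)
            else:
                raise FormatError(
                    f"cell {cell_id!r}: no pixel size in TIFF tags and no "
                    f"pixel_size_um manifest column"
                )
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise FormatError(f"cell {cell_id!r}: channel rasters differ in shape: {shapes}")
        channels = {name: np.asarray(a) for name, a in zip(CHANNELS, arrays)}
        cells.append(
            CellRecord(
                cell_id=cell_id,
                channels=channels,
                pixel_size=pixel_size,
                meta={"condition": str(row.condition), "replicate": str(row.replicate)},
            )
        )
        condition = str(row.condition)
        replicate = int(row.replicate)
    sample_id = manifest_path.stem
    logger.info("read sample %s: %d cells", sample_id, len(cells))
    return SampleManifest(sample_id=sample_id, cells=cells, condition=condition, replicate=replicate)


def write_sample(
    cells: Sequence[CellRecord],
    out_dir: str | Path,
    condition: str = "",
    replicate: int = 0,
    manifest_name: str = "manifest.csv",
) -> Path:
    """Write cells as per-cell multi-page TIFFs plus a manifest CSV.

    Rasters are stored as 16-bit unsigned; callers should quantize
    beforehand (the synthetic generator already emits integer-valued
    rasters).  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cell in cells:
        stack = np.stack([cell.channels[c] for c in CHANNELS]).astype(np.uint16)
        tiff_name = f"{cell.cell_id}.tiff"
        px_per_cm = 1e4 / cell.pixel_size
        tifffile.imwrite(
            out_dir / tiff_name,
            stack,
            photometric="minisblack",
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
        )
        rows.append(
            {
                "cell_id": cell.cell_id,
                "tiff_path": tiff_name,
                "condition": condition or cell.meta.get("condition", ""),
                "replicate": replicate or cell.meta.get("replicate", 0),
                "pixel_size_um": cell.pixel_size,
            }
        )
    manifest_path = out_dir / manifest_name
    pd.DataFrame(rows).to_csv(manifest_path, index=False)
    return manifest_path


# ---------------------------------------------------------------------------
# Feature-table I/O: CSV with "name[unit]" headers + provenance sidecar
# ---------------------------------------------------------------------------


def _provenance_path(path: Path) -> Path:
    return path.with_name(path.stem + ".provenance.json")


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a feature table as CSV (header ``name[unit]``) + JSON sidecar."""
    path = Path(path)
    df = table.df.copy()
    df.columns = [f"{name}[{table.unit(name)}]" for name in table.df.columns]
    try:
        df.to_csv(path, index=True, index_label="cell_id", float_format="%.17g")
    except OSError as exc:
        raise GolgiqError(f"cannot write feature table to {path}: {exc}") from exc
    _provenance_path(path).write_text(json.dumps(table.provenance, indent=2) + "\n")


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    df = pd.read_csv(path, index_col="cell_id")
    df.index = df.index.astype(str)
    renames = {}
    units = {}
    for col in df.columns:
        if col.endswith("]") and "[" in col:
            name, unit = col[:-1].rsplit("[", 1)
        else:
            name, unit = col, "au"
        renames[col] = name
        units[name] = unit
    df = df.rename(columns=renames)
    sidecar = _provenance_path(path)
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text())
    else:
        provenance = {name: {"unit": unit} for name, unit in units.items()}
    for name in df.columns:
        provenance.setdefault(name, {"unit": units.get(name, "au")})
    return FeatureTable(df, provenance)
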