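"""Population-level summaries and replicate statistics.

Turns per-cell gating labels into the numbers a fragmentation study
reports: percentages of intact / partially / fully fragmented Golgi
among eligible (single, focused) cells, apoptotic percentage,
cell-cycle and mitotic-phase breakdowns, replicate mean ± SEM and
two-tailed t-tests against a reference condition, and 2-D histogram
grids for density dot-plots of the fragmentation plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ifcio import FeatureTable, GolgiqError
from .gating import CYCLE_LABELS, GOLGI_LABELS, MITOTIC_LABELS, GatingResult

__all__ = [
    "PopulationSummary",
    "summarize",
    "ReplicateComparison",
    "compare_replicates",
    "density_plot_data",
    "plot_density",
    "plot_golgi_stacked_bars",
]


@dataclass
class PopulationSummary:
    """Percentages and counts for one gated sample.

    Golgi and apoptotic percentages use the eligible (singlet AND
    focused) denominator; mitotic-phase percentages use the G2M
    denominator.  ``flags`` records degenerate denominators instead of
    raising.
    """

    sample_id: str
    n_total: int
    n_eligible: int
    golgi_pct: dict[str, float]       # intact/partial/full, % of eligible-and-assigned
    apoptotic_pct: float
    cycle_pct: dict[str, float]       # % of eligible
    mitotic_pct: dict[str, float]     # % of G2M
    n_unassigned: int = 0
    flags: list[str] = field(default_factory=list)

    def as_row(self) -> dict[str, float | int | str]:
        row: dict[str, float | int | str] = {
            "sample_id": self.sample_id,
            "n_total": self.n_total,
            "n_eligible": self.n_eligible,
            "n_unassigned": self.n_unassigned,
            "apoptotic_pct": self.apoptotic_pct,
        }
        for k, v in self.golgi_pct.items():
            row[f"golgi_{k}_pct"] = v
        for k, v in self.cycle_pct.items():
            row[f"cycle_{k.replace('/', '_')}_pct"] = v
        for k, v in self.mitotic_pct.items():
            row[f"mitotic_{k}_pct"] = v
        return row


def summarize(result: GatingResult, sample_id: str = "sample") -> PopulationSummary:
    """Population summary of a gating result.

    Golgi class percentages are over eligible cells with an assigned
    label, so intact + partial + full = 100 (up to rounding); zero
    eligible cells yields zeroed percentages with a flag rather than a
    division error.
    """
    df = result.df
    if len(df) == 0:
        raise GolgiqError("summarize: empty gating result")
    eligible = result.eligible
    n_eligible = int(eligible.sum())
    flags: list[str] = []

    golgi = df.loc[eligible, "golgi"]
    assigned = golgi[golgi.isin(GOLGI_LABELS)]
    n_unassigned = int(n_eligible - len(assigned))
    if len(assigned):
        golgi_pct = {k: 100.0 * float((assigned == k).sum()) / len(assigned) for k in GOLGI_LABELS}
    else:
        golgi_pct = {k: 0.0 for k in GOLGI_LABELS}
        flags.append("no_assigned_golgi_cells")

    if n_eligible:
        apoptotic_pct = 100.0 * float(df.loc[eligible, "apoptotic"].sum()) / n_eligible
        cycle_pct = {
            k: 100.0 * float((df.loc[eligible, "cycle"] == k).sum()) / n_eligible
            for k in CYCLE_LABELS
        }
    else:
        apoptotic_pct = 0.0
        cycle_pct = {k: 0.0 for k in CYCLE_LABELS}
        flags.append("no_eligible_cells")

    g2m = eligible & (df["cycle"] == "G2M")
    n_g2m = int(g2m.sum())
    if n_g2m:
        mitotic_pct = {
            k: 100.0 * float((df.loc[g2m, "mitotic"] == k).sum()) / n_g2m for k in MITOTIC_LABELS
        }
    else:
        mitotic_pct = {k: 0.0 for k in MITOTIC_LABELS}

    return PopulationSummary(
        sample_id=sample_id,
        n_total=int(len(df)),
        n_eligible=n_eligible,
        golgi_pct=golgi_pct,
        apoptotic_pct=apoptotic_pct,
        cycle_pct=cycle_pct,
        mitotic_pct=mitotic_pct,
        n_unassigned=n_unassigned,
        flags=flags,
    )


@dataclass
class ReplicateComparison:
    """Replicate mean ± SEM per condition and t-tests vs a reference.

    ``table`` has one row per (condition, quantity) with columns mean,
    sem, n, t, p, significant.  Conditions with a single replicate get
    means but flagged-unavailable tests (NaN t/p).
    """

    reference: str
    table: pd.DataFrame


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed Welch t-test; degenerate equal constant samples → (0, 1)."""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_replicates(
    summaries: Mapping[str, Sequence[PopulationSummary]],
    reference: str,
    quantities: Sequence[str] = ("golgi_intact_pct", "golgi_partial_pct", "golgi_full_pct", "apoptotic_pct"),
    pooled: bool = False,
    alpha: float = 0.05,
) -> ReplicateComparison:
    """Compare per-condition replicate percentages against a reference.

    ``summaries`` groups :class:`PopulationSummary` objects (one per
    replicate) by condition.  Means and SEM (= sd/sqrt(n)) are reported
    per quantity; each non-reference condition is tested against the
    reference with a two-tailed t-test (Welch by default, pooled-variance
    Student's with ``pooled=True``), flagged significant at ``alpha``.
    """
    if reference not in summaries:
        raise GolgiqError(f"reference condition {reference!r} not in summaries")
    values: dict[str, dict[str, np.ndarray]] = {}
    for cond, items in summaries.items():
        rows = pd.DataFrame([s.as_row() for s in items])
        values[cond] = {q: rows[q].to_numpy(dtype=float) for q in quantities}

    out_rows = []
    for cond, qs in values.items():
        for q in quantities:
            v = qs[q]
            n = len(v)
            mean = float(v.mean())
            sem = float(v.std(ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
            t = p = math.nan
            sig = False
            ref_v = values[reference][q]
            if cond != reference and n >= 2 and len(ref_v) >= 2:
                if pooled:
                    t, p = (float(x) for x in sps.ttest_ind(ref_v, v, equal_var=True))
                else:
                    t, p = _welch(ref_v, v)
                sig = bool(p < alpha)
            out_rows.append(
                {"condition": cond, "quantity": q, "n": n, "mean": mean, "sem": sem,
                 "t": t, "p": p, "significant": sig}
            )
    return ReplicateComparison(reference, pd.DataFrame(out_rows))


def density_plot_data(
    table: FeatureTable,
    x_feature: str,
    y_feature: str,
    bins: int | tuple[int, int] = 64,
    x_range: tuple[float, float] | None = None,
    y_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned counts for a density dot-plot of two features.

    Returns (counts, x_edges, y_edges) with counts[i, j] the number of
    cells in x-bin i and y-bin j; NaN-valued cells are ignored.  Ranges
    default to the finite data extent (or (0, 1) for an empty table).
    """
    for feat in (x_feature, y_feature):
        if feat not in table.df.columns:
            raise GolgiqError(f"density_plot_data: no column {feat!r}")
    sub = table.df[[x_feature, y_feature]].dropna()
    x = sub[x_feature].to_numpy(dtype=float)
    y = sub[y_feature].to_numpy(dtype=float)
    if x_range is None:
        x_range = (float(x.min()), float(x.max())) if len(x) else (0.0, 1.0)
    if y_range is None:
        y_range = (float(y.min()), float(y.max())) if len(y) else (0.0, 1.0)
    if isinstance(bins, int):
        bins = (bins, bins)
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins, range=(x_range, y_range))
    return counts, x_edges, y_edges


def plot_density(
    table: FeatureTable,
    x_feature: str,
    y_feature: str,
    path: str,
    bins: int = 64,
    title: str = "",
) -> None:
    """Export a density dot-plot of two features as PNG/SVG (by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts, xe, ye = density_plot_data(table, x_feature, y_feature, bins=bins)
    fig, ax = plt.subplots(figsize=(5, 4))
    with np.errstate(divide="ignore"):
        ax.pcolormesh(xe, ye, np.log1p(counts.T), cmap="viridis")
    ax.set_xlabel(f"{x_feature} [{table.unit(x_feature)}]")
    ax.set_ylabel(f"{y_feature} [{table.unit(y_feature)}]")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_golgi_stacked_bars(summaries: Sequence[PopulationSummary], path: str) -> None:
    """Stacked intact/partial/full percentage bars, one per sample."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [s.sample_id for s in summaries]
    fig, ax = plt.subplots(figsize=(1.2 + 0.8 * len(names), 4))
    bottom = np.zeros(len(names))
    colors = {"intact": "#4c72b0", "partial": "#dd8452", "full": "#c44e52"}
    for cls in GOLGI_LABELS:
        vals = np.array([s.golgi_pct[cls] for s in summaries])
        ax.bar(names, vals, bottom=bottom, label=cls, color=colors[cls])
        bottom += vals
    ax.set_ylabel("% of eligible cells")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
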