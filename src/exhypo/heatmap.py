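"""Traffic-light risk grid over starting glucose x duration x trend panel.

The grid scores every (glucose, duration) cell with the fold-ensemble mean
probability, once for the stable/rising panel and once for the falling
panel, and bins each cell into four categories: very low (<1%, dark
green), low (1-5%, light green), moderate (5-20%, amber), high (>20%,
red).  Intervals are left-closed/right-open, with the top bin closed at 1.
Duration is capped at 60 min, where predictive performance degrades.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelError, TrainedEnsemble, predict_ensemble

#: (name, colour, lower, upper) — [lower, upper) except the last bin
RISK_CATEGORIES = [
    ("very_low", "dark_green", 0.00, 0.01),
    ("low", "light_green", 0.01, 0.05),
    ("moderate", "amber", 0.05, 0.20),
    ("high", "red", 0.20, 1.00),
]
CATEGORY_ORDER = [name for name, *_ in RISK_CATEGORIES]
_HEX = {"dark_green": "#1a7a3a", "light_green": "#8fd18f", "amber": "#f0b429", "red": "#d64545"}

PANELS = ("stable_or_rising", "falling")

#: required simplified feature set, in model order
GRID_FEATURES = ["starting_glucose", "duration_min", "roc_falling"]


@dataclass(frozen=True)
class RiskCategory:
    value: str
    colour: str
    lower: float
    upper: float


@dataclass
class RiskGrid:
    """Cell table: (glucose, duration, panel) -> probability + category."""

    cells: pd.DataFrame  # columns: glucose, duration, panel, probability, category
    glucose_axis: np.ndarray
    duration_axis: np.ndarray


def categorize(p: float) -> RiskCategory:
    """Map a probability to its traffic-light category."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    for name, colour, lo, hi in RISK_CATEGORIES:
        if lo <= p < hi:
            return RiskCategory(name, colour, lo, hi)
    return RiskCategory("high", "red", 0.20, 1.00)  # p == 1.0


def categorize_many(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must be in [0, 1]")
    edges = [c[2] for c in RISK_CATEGORIES] + [1.0]
    idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(CATEGORY_ORDER) - 1)
    return np.array(CATEGORY_ORDER, dtype=object)[idx]


def build_grid(
    ensemble: TrainedEnsemble,
    glucose_range: tuple[float, float] = (4.0, 14.0),
    glucose_step: float = 0.5,
    duration_range: tuple[float, float] = (10.0, 60.0),
    duration_step: float = 5.0,
) -> RiskGrid:
    """Score every grid cell for both trend panels.

    The ensemble must be trained on exactly the three simplified features
    (starting glucose, duration, binary falling trend); anything else is an
    error because the grid could not supply the remaining inputs.
    """
    if sorted(ensemble.features) != sorted(GRID_FEATURES):
        raise ModelError(
            f"heatmap requires features {GRID_FEATURES}, ensemble has {ensemble.features}"
        )
    if duration_range[1] > 60.0:
        raise ModelError("duration axis is capped at 60 min")
    glucose_axis = np.round(
        np.arange(glucose_range[0], glucose_range[1] + 1e-9, glucose_step), 3
    )
    duration_axis = np.round(
        np.arange(duration_range[0], duration_range[1] + 1e-9, duration_step), 3
    )
    frames = []
    for panel, falling in zip(PANELS, (0.0, 1.0)):
        gg, dd = np.meshgrid(glucose_axis, duration_axis, indexing="ij")
        rows = pd.DataFrame(
            {
                "starting_glucose": gg.ravel(),
                "duration_min": dd.ravel(),
                "roc_falling": falling,
            }
        )
        preds = predict_ensemble(ensemble, rows)
        frames.append(
            pd.DataFrame(
                {
                    "glucose": rows["starting_glucose"],
                    "duration": rows["duration_min"],
                    "panel": panel,
                    "probability": preds["mean"].to_numpy(),
                }
            )
        )
    cells = pd.concat(frames, ignore_index=True)
    cells["category"] = categorize_many(cells["probability"])
    return RiskGrid(cells=cells, glucose_axis=glucose_axis, duration_axis=duration_axis)


def grid_calibration(predictions, labels) -> pd.DataFrame:
    """Observed hypoglycaemia rate and count per traffic-light category."""
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(p) == 0:
        raise ValueError("empty dataset")
    cats = categorize_many(p)
    rows = []
    for name, colour, lo, hi in RISK_CATEGORIES:
        mask = cats == name
        n = int(mask.sum())
        rows.append(
            {
                "category": name,
                "colour": colour,
                "nominal_lower": lo,
                "nominal_upper": hi,
                "n": n,
                "observed_rate_pct": 100.0 * float(y[mask].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def monotone_audit(grid: RiskGrid, tolerance: float = 0.01) -> pd.DataFrame:
    """Adjacent-cell monotonicity violations.

    Clinically, risk should not increase with starting glucose (duration
    and panel held fixed) nor decrease with duration (glucose and panel
    held fixed).  Violations beyond ``tolerance`` are listed; the audit is
    deterministic given a grid.
    """
    viols = []
    for panel in PANELS:
        sub = grid.cells[grid.cells["panel"] == panel]
        pivot = sub.pivot(index="glucose", columns="duration", values="probability")
        prob = pivot.to_numpy()
        dg = np.diff(prob, axis=0)  # along increasing glucose: should be <= tol
        for i, j in zip(*np.where(dg > tolerance)):
            viols.append(
                {
                    "panel": panel,
                    "axis": "glucose",
                    "glucose": float(pivot.index[i + 1]),
                    "duration": float(pivot.columns[j]),
                    "increase": float(dg[i, j]),
                }
            )
        dd = np.diff(prob, axis=1)  # along increasing duration: should be >= -tol
        for i, j in zip(*np.where(dd < -tolerance)):
            viols.append(
                {
                    "panel": panel,
                    "axis": "duration",
                    "glucose": float(pivot.index[i]),
                    "duration": float(pivot.columns[j + 1]),
                    "increase": float(-dd[i, j]),
                }
            )
    return pd.DataFrame(viols, columns=["panel", "axis", "glucose", "duration", "increase"])


def adjacent_pair_count(grid: RiskGrid) -> int:
    ng, nd = len(grid.glucose_axis), len(grid.duration_axis)
    return 2 * ((ng - 1) * nd + ng * (nd - 1))


def render(grid: RiskGrid, output_stem, mgdl: bool = False) -> dict[str, Path]:
    """Two-panel heatmap image plus a machine-readable cell CSV.

    ``mgdl`` relabels the glucose axis in mg/dl; values remain mmol/l
    internally.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap
    from matplotlib.patches import Patch

    from .cgm import mmol_to_mgdl_display

    output_stem = Path(output_stem)
    output_stem.parent.mkdir(parents=True, exist_ok=True)
    cmap = ListedColormap([_HEX[c[1]] for c in RISK_CATEGORIES])
    norm = BoundaryNorm([0.0, 0.01, 0.05, 0.20, 1.0], cmap.N)

    fig, axes = plt.subplots(1, 2, figsize=(11, 5), sharey=True)
    titles = {"stable_or_rising": "Stable / rising trend", "falling": "Falling trend"}
    for ax, panel in zip(axes, PANELS):
        sub = grid.cells[grid.cells["panel"] == panel]
        pivot = sub.pivot(index="duration", columns="glucose", values="probability")
        ax.pcolormesh(
            pivot.columns.to_numpy(),
            pivot.index.to_numpy(),
            pivot.to_numpy(),
            cmap=cmap,
            norm=norm,
            shading="nearest",
        )
        ax.set_title(titles[panel])
        xlabel = "Starting glucose (mg/dl)" if mgdl else "Starting glucose (mmol/l)"
        ax.set_xlabel(xlabel)
        if mgdl:
            ticks = ax.get_xticks()
            ax.set_xticks(ticks)
            ax.set_xticklabels([mmol_to_mgdl_display(t) if t >= 0 else "" for t in ticks])
            ax.set_xlim(grid.glucose_axis.min(), grid.glucose_axis.max())
    axes[0].set_ylabel("Planned duration (min)")
    legend = [
        Patch(facecolor=_HEX[colour], label=f"{name.replace('_', ' ')} ({lo:.0%}–{hi:.0%})")
        for name, colour, lo, hi in RISK_CATEGORIES
    ]
    axes[1].legend(handles=legend, loc="upper left", bbox_to_anchor=(1.02, 1.0), frameon=False)
    fig.tight_layout()
    png = output_stem.with_suffix(".png")
    fig.savefig(png, dpi=150)
    plt.close(fig)

    csv = output_stem.with_suffix(".csv")
    grid.cells.to_csv(csv, index=False, float_format="%.6f")
    return {"image": png, "csv": csv}
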