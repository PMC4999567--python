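"""Color-by-attribute scatter rendering with linked selection.

The interactions an expert performs on a visual-clustering display
(mouse-wheel color cycling, click selection linked across plots) are
exposed here as pure state transitions over immutable :class:`PlotState`
/ :class:`LinkedView` values plus file exports, which keeps every
behavior scriptable and testable without a GUI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ContractError, DanglingReferenceError
from .preprocess import AnalysisTable
from .sammon import Embedding

#: colorblind-safe categorical palette (Okabe-Ito)
CATEGORICAL_PALETTE = (
    "#0072B2",
    "#E69F00",
    "#009E73",
    "#CC79A7",
    "#56B4E9",
    "#D55E00",
    "#F0E442",
    "#999999",
)

#: the rupture attribute keeps the conventional clinical coloring:
#: ruptured red, non-ruptured white
RUPTURE_COLORS = {"True": "#D62728", "False": "#FFFFFF"}


@dataclass(frozen=True)
class PlotState:
    """One scatter plot: an embedding colored by one table attribute."""

    embedding: Embedding
    table: AnalysisTable
    color_attribute: str
    selection: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.color_attribute not in self.table.columns:
            raise DanglingReferenceError(
                f"color attribute {self.color_attribute!r} not in table columns"
            )
        universe = set(self.embedding.row_ids)
        stray = self.selection - universe
        if stray:
            raise ContractError(f"selection outside row universe: {sorted(stray)[:5]}")

    @property
    def attributes(self) -> list[str]:
        return list(self.table.columns)


@dataclass(frozen=True)
class LinkedView:
    """Several plots over one record universe sharing a single selection."""

    plots: tuple[PlotState, ...]
    selection: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        universes = {tuple(p.embedding.row_ids) for p in self.plots}
        if len(universes) > 1:
            raise ContractError("all linked plots must share one row_id universe")
        for p in self.plots:
            if p.selection != self.selection:
                raise ContractError("every plot's selection must equal the shared selection")

    @property
    def row_ids(self) -> list[str]:
        return list(self.plots[0].embedding.row_ids) if self.plots else []


def link(plots: Sequence[PlotState]) -> LinkedView:
    """Link plots into one view, resetting selections to a shared empty set."""
    synced = tuple(replace(p, selection=frozenset()) for p in plots)
    return LinkedView(plots=synced, selection=frozenset())


# ---------------------------------------------------------------------------
# color handling
# ---------------------------------------------------------------------------


def _color_values(plot: PlotState) -> pd.Series:
    order = [str(i) for i in plot.embedding.row_ids]
    col = plot.table.data[plot.color_attribute]
    col.index = col.index.astype(str)
    return col.reindex(order)


def categorical_palette(plot: PlotState) -> dict[str, str]:
    """Stable category -> color mapping (sorted category order)."""
    spec = plot.table.spec(plot.color_attribute)
    vals = _color_values(plot)
    if spec.kind == "boolean" or set(map(str, vals.dropna().unique())) <= {"True", "False"}:
        return dict(RUPTURE_COLORS) if "Ruptured" in plot.color_attribute else {
            "False": CATEGORICAL_PALETTE[0],
            "True": CATEGORICAL_PALETTE[1],
        }
    cats = sorted(map(str, vals.dropna().unique()))
    return {c: CATEGORICAL_PALETTE[i % len(CATEGORICAL_PALETTE)] for i, c in enumerate(cats)}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def render(plot: PlotState, out_base: Union[str, Path]) -> dict[str, Path]:
    """Write ``<out_base>.png`` and ``<out_base>.csv`` for a plot state.

    The CSV export carries (row_id, x, y, color value, selected flag) so
    the picture can be reconstructed or re-styled without the package.
    Rendering never mutates the plot state.
    """
    out_base = Path(out_base)
    out_base.parent.mkdir(parents=True, exist_ok=True)
    coords = plot.embedding.coords
    vals = _color_values(plot)
    spec = plot.table.spec(plot.color_attribute)
    selected = np.array([rid in plot.selection for rid in plot.embedding.row_ids])

    fig, ax = plt.subplots(figsize=(7, 6))
    try:
        if spec.kind == "numeric":
            sc = ax.scatter(
                coords[:, 0], coords[:, 1], c=vals.to_numpy(dtype=float), cmap="viridis", s=18
            )
            fig.colorbar(sc, ax=ax, label=f"{plot.color_attribute}" + (f" [{spec.unit}]" if spec.unit else ""))
        else:
            palette = categorical_palette(plot)
            svals = vals.map(lambda v: str(v) if v is not None else "missing")
            for cat, color in palette.items():
                mask = (svals == cat).to_numpy()
                if mask.any():
                    ax.scatter(
                        coords[mask, 0],
                        coords[mask, 1],
                        c=color,
                        edgecolors="#444444",
                        linewidths=0.4,
                        s=18,
                        label=cat,
                    )
            ax.legend(title=plot.color_attribute, fontsize=8)
        if selected.any():
            ax.scatter(
                coords[selected, 0],
                coords[selected, 1],
                facecolors="none",
                edgecolors="#000000",
                linewidths=1.2,
                s=60,
                label="selected",
            )
        ax.set_xlabel("dimension 1")
        ax.set_ylabel("dimension 2")
        ax.set_title(f"colored by {plot.color_attribute}")
        png_path = out_base.with_suffix(".png")
        fig.savefig(png_path, dpi=120)
    finally:
        plt.close(fig)

    csv_path = out_base.with_suffix(".csv")
    pd.DataFrame(
        {
            "row_id": plot.embedding.row_ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "color_value": vals.values,
            "selected": selected,
        }
    ).to_csv(csv_path, index=False)
    return {"image": png_path, "data": csv_path}


def cycle_color(plot: PlotState, direction: int = 1) -> PlotState:
    """Next/previous color attribute in declared order, wrapping around."""
    attrs = plot.attributes
    if not attrs:
        raise ContractError("no eligible color attributes")
    idx = attrs.index(plot.color_attribute)
    return replace(plot, color_attribute=attrs[(idx + direction) % len(attrs)])


def select(
    view: LinkedView,
    ids: Optional[Iterable[str]] = None,
    predicate: Optional[Callable[[pd.DataFrame], "pd.Series"]] = None,
) -> LinkedView:
    """Set the shared selection by explicit ids or by a row predicate.

    ``predicate`` receives the analysis table of the first plot and must
    return a boolean mask; the matching row ids become the selection on
    every linked plot.  Unknown ids raise an error listing the offenders.
    """
    if (ids is None) == (predicate is None):
        raise ContractError("provide exactly one of ids or predicate")
    universe = set(view.row_ids)
    if ids is not None:
        chosen = {str(i) for i in ids}
        stray = chosen - universe
        if stray:
            raise ContractError(f"unknown row ids: {sorted(stray)}")
    else:
        table = view.plots[0].table
        df = table.data.copy()
        df.index = df.index.astype(str)
        mask = predicate(df)
        chosen = {str(i) for i in df.index[np.asarray(mask, dtype=bool)]} & universe
    sel = frozenset(chosen)
    plots = tuple(replace(p, selection=sel) for p in view.plots)
    return LinkedView(plots=plots, selection=sel)


def export_selection(view: LinkedView, path: Union[str, Path]) -> Path:
    """Write the selected records as a CSV slice of the analysis table."""
    table = view.plots[0].table
    df = table.data.copy()
    df.index = df.index.astype(str)
    sel = df.loc[sorted(view.selection)]
    path = Path(path)
    sel.to_csv(path, index_label="id")
    return path
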