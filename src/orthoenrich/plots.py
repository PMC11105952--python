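"""Visualization of enrichment tables: dot plots, bar charts, volcano plots.

The data-extraction layer (:func:`dot_plot_data`, :func:`bar_counts`,
:func:`volcano_coords`) is pure and unit-testable; the rendering functions
are thin matplotlib wrappers around it.  Visual encodings follow the
conventions of enrichment dot plots: dot color carries the signed
significance score -log10(p) x (+1 up / -1 down), dot size the percentage
of significant genes in the set, and orthology-derived sets are highlighted
so novel (human-only) annotations stand out.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .genesets import AnnotationOrganism
from .enrich import Method

logger = logging.getLogger(__name__)

__all__ = [
    "PlotSpec",
    "dot_plot_data",
    "dot_plot",
    "bar_counts",
    "bar_chart",
    "volcano_coords",
    "volcano_plot",
]


class ImageFormat(str, enum.Enum):
    PNG = "png"
    SVG = "svg"
    PDF = "pdf"


@dataclass
class PlotSpec:
    """Rendering options shared by the plot functions."""

    top_n: int = 10
    output_path: str | Path = "plot.png"
    format: ImageFormat | None = None  # inferred from the path suffix if None

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.format is None:
            suffix = Path(self.output_path).suffix.lstrip(".").lower() or "png"
            self.format = ImageFormat(suffix)


def _signed_score(table: pd.DataFrame) -> np.ndarray:
    """-log10(p) signed +1 for up-direction records, -1 for down."""
    sign = np.where(table["direction"].to_numpy() == "down", -1.0, 1.0)
    return -np.log10(table["pvalue"].to_numpy()) * sign


def dot_plot_data(table: pd.DataFrame, top_n: int = 10) -> pd.DataFrame:
    """Select the ``top_n`` lowest-p up records and ``top_n`` lowest-p down
    records and attach plotting channels (score, size, orthology flag).

    A direction with no records simply contributes nothing (logged).
    """
    parts = []
    for direction in ("up", "down"):
        sub = table[table["direction"] == direction]
        if sub.empty:
            logger.info("no %sregulated records; panel omitted", direction)
            continue
        sub = sub.sort_values(["pvalue", "set_id"], kind="mergesort").head(top_n)
        parts.append(sub)
    if not parts:
        # nondirectional table: fall back to the single lowest-p slice
        parts = [table.sort_values(["pvalue", "set_id"], kind="mergesort").head(top_n)]
    data = pd.concat(parts, ignore_index=True)
    data = data.assign(
        score=_signed_score(data),
        size=data["pct_sig_genes"].to_numpy(),
        is_orthology=(
            data["annotation_organism"]
            == AnnotationOrganism.HUMAN_VIA_ORTHOLOGY.value
        ),
    )
    return data


def dot_plot(table: pd.DataFrame, spec: PlotSpec) -> Path:
    """Dot plot of the top up- and downregulated sets.

    Color is the signed significance score on a diverging scale anchored at
    zero (up/down visually symmetric); size is the percentage of
    significant genes; orthology-derived sets get a highlighted edge.
    """
    if table.empty:
        raise ValueError("enrichment table is empty")
    data = dot_plot_data(table, spec.top_n)
    order = data.sort_values("score")
    vmax = float(np.nanmax(np.abs(order["score"]))) or 1.0
    fig, ax = plt.subplots(figsize=(7, max(3, 0.35 * len(order) + 1.5)))
    edge = np.where(order["is_orthology"], "gold", "none")
    sc = ax.scatter(
        order["score"],
        np.arange(len(order)),
        c=order["score"],
        cmap="RdBu_r",
        vmin=-vmax,
        vmax=vmax,
        s=20 + 3 * order["size"],
        edgecolors=edge,
        linewidths=1.5,
    )
    ax.set_yticks(np.arange(len(order)))
    ax.set_yticklabels(order["set_name"].where(order["set_name"] != "", order["set_id"]))
    ax.axvline(0, color="0.8", lw=0.8)
    ax.set_xlabel("signed significance  -log10(p) x direction")
    fig.colorbar(sc, ax=ax, label="signed -log10(p)")
    fig.tight_layout()
    out = Path(spec.output_path)
    fig.savefig(out, format=spec.format.value)
    plt.close(fig)
    return out


def bar_counts(table: pd.DataFrame, group_by: str = "direction") -> pd.Series:
    """Record counts per group; zero-count groups among the observed
    category levels are retained."""
    if table.empty:
        raise ValueError("enrichment table is empty")
    if group_by not in ("direction", "source_db", "annotation_organism"):
        raise ValueError(f"cannot group by {group_by!r}")
    if group_by == "source_db" and "source_db" not in table.columns:
        raise ValueError("table has no source_db column")
    counts = table.groupby(group_by, observed=False).size()
    return counts


def bar_chart(table: pd.DataFrame, spec: PlotSpec, group_by: str = "direction") -> Path:
    counts = bar_counts(table, group_by)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(counts.index.astype(str), counts.to_numpy(), color="steelblue")
    ax.set_xlabel(group_by)
    ax.set_ylabel("number of gene sets")
    fig.tight_layout()
    out = Path(spec.output_path)
    fig.savefig(out, format=spec.format.value)
    plt.close(fig)
    return out


def volcano_coords(table: pd.DataFrame) -> pd.DataFrame:
    """x = effect on a log scale (log odds ratio for Fisher, beta for the
    logistic model), y = -log10(p)."""
    if table.empty:
        raise ValueError("enrichment table is empty")
    effect = table["effect"].to_numpy(dtype=float)
    is_fisher = table["method"].to_numpy() == Method.FISHER.value
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(is_fisher, np.log(effect), effect)
    y = -np.log10(table["pvalue"].to_numpy())
    return pd.DataFrame({"set_id": table["set_id"], "x": x, "y": y})


def volcano_plot(table: pd.DataFrame, spec: PlotSpec, alpha: float = 0.05) -> Path:
    coords = volcano_coords(table)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(coords["x"], coords["y"], s=12, alpha=0.8, color="0.3")
    ax.axhline(-np.log10(alpha), color="firebrick", lw=0.8, ls="--")
    ax.set_xlabel("effect (log odds ratio / beta)")
    ax.set_ylabel("-log10(p)")
    fig.tight_layout()
    out = Path(spec.output_path)
    fig.savefig(out, format=spec.format.value)
    plt.close(fig)
    return out
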