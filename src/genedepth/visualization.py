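"""Plots: stacked score bars, group box plots, and colored module graphs.

Every plotting function writes the figure AND a machine-readable backing
table (TSV next to the image) holding exactly the numbers drawn, so the
aggregation logic is testable without pixel comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.colors import Normalize, to_hex

from .scoring import ScoreTable, scores_to_long

__all__ = ["PlotSpec", "PlotError", "bar_plot", "box_plot", "module_plot", "tukey_quartiles"]

FORMATS = ("png", "svg", "pdf")

#: Fill color for reactions whose score could not be computed.
MISSING_COLOR = "#bbbbbb"


class PlotError(ValueError):
    """Raised when a plot request cannot be satisfied."""


@dataclass
class PlotSpec:
    """What to draw and where to write it.

    x / fill / group name either the built-in variables ('sample',
    'query', 'taxon') or a column of the supplied sample-metadata table;
    the output format is taken from the path suffix (png, svg, or pdf).
    """

    path: str | Path
    x: str = "sample"
    fill: str | None = None
    group: str | None = None
    cmap: str = "viridis"
    aggregate: str = "sum"

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        fmt = self.path.suffix.lstrip(".")
        if fmt not in FORMATS:
            raise PlotError(f"output format {fmt!r} not in {FORMATS}")
        if self.aggregate not in ("sum", "mean"):
            raise PlotError("aggregate must be 'sum' or 'mean'")

    @property
    def backing_path(self) -> Path:
        return self.path.with_suffix(self.path.suffix + ".tsv")


def _resolve(long: pd.DataFrame, var: str, metadata: pd.DataFrame | None) -> pd.Series:
    """Map each tidy record to its value of the grouping variable."""
    if var in long.columns and var != "score":
        return long[var]
    if metadata is not None and var in metadata.columns:
        mapped = long["sample"].map(metadata[var])
        if mapped.isna().any():
            missing = sorted(set(long.loc[mapped.isna(), "sample"]))
            raise PlotError(f"samples missing from metadata for {var!r}: {missing}")
        return mapped
    available = [c for c in long.columns if c != "score"] + (
        list(metadata.columns) if metadata is not None else []
    )
    raise PlotError(f"unknown plot variable {var!r}; available: {available}")


def bar_plot(
    scores: ScoreTable,
    spec: PlotSpec,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Bar plot of scores aggregated over the x (and optional fill) variable.

    Scores are summed (or averaged) within each group; with a fill
    variable the bars are stacked, matching the "contribution of each
    taxon to the total" reading of stratified scores.  Returns the
    backing table of plotted heights.
    """
    long = scores_to_long(scores)
    if long.empty:
        raise PlotError("nothing to plot: score table has no defined cells")
    long = long.assign(_x=_resolve(long, spec.x, metadata))
    keys = ["_x"]
    if spec.fill is not None:
        long = long.assign(_fill=_resolve(long, spec.fill, metadata))
        keys.append("_fill")
    agg = long.groupby(keys, sort=True)["score"].agg(spec.aggregate).reset_index()
    agg = agg.rename(columns={"_x": spec.x, "_fill": spec.fill or "fill"})
    backing = agg[[c for c in agg.columns if c != "fill" or spec.fill]]

    fig, ax = plt.subplots(figsize=(max(4, agg[spec.x].nunique()), 4))
    if spec.fill is None:
        ax.bar(agg[spec.x].astype(str), agg["score"], color="#4878a8")
    else:
        wide = agg.pivot(index=spec.x, columns=spec.fill, values="score").fillna(0.0)
        bottom = np.zeros(len(wide))
        cmap = colormaps[spec.cmap]
        for i, col in enumerate(wide.columns):
            ax.bar(
                wide.index.astype(str),
                wide[col],
                bottom=bottom,
                label=str(col),
                color=cmap(i / max(1, len(wide.columns) - 1)),
            )
            bottom += wide[col].to_numpy()
        ax.legend(title=spec.fill, fontsize="small")
    ax.set_xlabel(spec.x)
    ax.set_ylabel("copy-number score")
    fig.tight_layout()
    fig.savefig(spec.path)
    plt.close(fig)
    backing.to_csv(spec.backing_path, sep="\t", index=False)
    return backing


def tukey_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """(q1, median, q3) by the median-exclusive (Tukey hinge) convention."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n == 0:
        raise ValueError("no values")
    med = float(np.median(v))
    half = n // 2
    lower, upper = v[:half], v[n - half :]
    if half == 0:  # single observation
        return med, med, med
    return float(np.median(lower)), med, float(np.median(upper))


def box_plot(
    scores: ScoreTable,
    spec: PlotSpec,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Box plot of per-sample scores split by a sample-metadata group.

    Undefined cells are excluded (with a count warning inherited from the
    tidy reshape); empty groups are omitted with a warning.  Quartiles
    follow the median-exclusive (Tukey) convention.  Returns the backing
    table of (group, sample, query, score) records.
    """
    if spec.group is None:
        raise PlotError("box_plot needs spec.group")
    long = scores_to_long(scores)
    if long.empty:
        raise PlotError("nothing to plot: score table has no defined cells")
    long = long.assign(_group=_resolve(long, spec.group, metadata))

    groups = sorted(long["_group"].dropna().unique())
    declared = (
        sorted(metadata[spec.group].dropna().unique())
        if spec.group in metadata.columns
        else groups
    )
    empty = [g for g in declared if g not in groups]
    if empty:
        warnings.warn(f"omitting empty group(s): {empty}", stacklevel=2)

    stats = []
    for g in groups:
        vals = long.loc[long["_group"] == g, "score"].to_numpy()
        q1, med, q3 = tukey_quartiles(vals)
        iqr = q3 - q1
        lo = vals[vals >= q1 - 1.5 * iqr].min()
        hi = vals[vals <= q3 + 1.5 * iqr].max()
        stats.append(
            {
                "label": str(g),
                "q1": q1,
                "med": med,
                "q3": q3,
                "whislo": float(lo),
                "whishi": float(hi),
                "fliers": vals[(vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)],
            }
        )

    fig, ax = plt.subplots(figsize=(max(4, len(groups)), 4))
    ax.bxp(stats, showfliers=True)
    ax.set_xlabel(spec.group)
    ax.set_ylabel("copy-number score")
    fig.tight_layout()
    fig.savefig(spec.path)
    plt.close(fig)

    backing = long.rename(columns={"_group": "group"})[
        [c for c in ["group", "sample", "query", "taxon", "score"] if c in long.columns or c in ("group",)]
    ]
    backing.to_csv(spec.backing_path, sep="\t", index=False)
    return backing


def _layered_layout(graph: nx.DiGraph) -> dict[str, tuple[float, float]]:
    """Deterministic top-to-bottom layout by topological generation."""
    if nx.is_directed_acyclic_graph(graph):
        layers = [sorted(layer) for layer in nx.topological_generations(graph)]
    else:  # cycles (e.g. regenerating cofactors): fall back to BFS layers
        roots = sorted(n for n in graph if graph.in_degree(n) == 0) or sorted(graph)[:1]
        seen, layers, frontier = set(roots), [sorted(roots)], roots
        while frontier:
            nxt = sorted(
                {m for n in frontier for m in graph.successors(n)} - seen
            )
            if not nxt:
                break
            layers.append(nxt)
            seen.update(nxt)
            frontier = nxt
        rest = sorted(set(graph) - seen)
        if rest:
            layers.append(rest)
    pos = {}
    for depth, layer in enumerate(layers):
        for i, node in enumerate(layer):
            pos[node] = (i - (len(layer) - 1) / 2, -depth)
    return pos


def module_plot(graph: nx.DiGraph, spec: PlotSpec) -> pd.DataFrame:
    """Draw an annotated module graph: white compounds, score-colored reactions.

    Reactions are filled from a linear color scale anchored at 0 (so
    absent functions look the same across figures) up to the maximum
    reaction score; reactions with an unset score get a sentinel grey and
    a warning.  Returns the node-color backing table.
    """
    reactions = [n for n, d in graph.nodes(data=True) if d.get("kind") == "reaction"]
    if any("score" not in graph.nodes[n] for n in reactions):
        raise PlotError("graph is not annotated; run annotate_module first")
    scores = {n: graph.nodes[n]["score"] for n in reactions}
    unset = sorted(n for n, s in scores.items() if s is None)
    if unset:
        warnings.warn(f"reaction(s) with unset scores drawn in sentinel color: {unset}", stacklevel=2)
    vmax = max([s for s in scores.values() if s is not None], default=0.0)
    norm = Normalize(vmin=0.0, vmax=vmax if vmax > 0 else 1.0)
    cmap = colormaps[spec.cmap]

    rows = []
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        if data["kind"] == "compound":
            color = "#ffffff"
            score = ""
        elif scores[node] is None:
            color = MISSING_COLOR
            score = ""
        else:
            color = to_hex(cmap(norm(scores[node])))
            score = scores[node]
        rows.append({"node": node, "kind": data["kind"], "score": score, "color": color})
    backing = pd.DataFrame(rows, columns=["node", "kind", "score", "color"])

    pos = _layered_layout(graph)
    fig, ax = plt.subplots(figsize=(6, 6))
    order = list(backing["node"])
    nx.draw_networkx(
        graph,
        pos=pos,
        ax=ax,
        nodelist=order,
        node_color=list(backing["color"]),
        edgecolors="#333333",
        labels={n: graph.nodes[n].get("label", n) for n in graph},
        font_size=7,
        node_size=900,
        arrows=True,
    )
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(spec.path)
    plt.close(fig)
    backing.to_csv(spec.backing_path, sep="\t", index=False)
    return backing
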