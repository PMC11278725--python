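"""Metabolic-module graphs and reaction-level score annotation.

A KEGG-style module is represented as a bipartite directed graph:
compound nodes alternate with reaction nodes, and each reaction carries
the set of KEGG ortholog (KO) ids of the enzymes able to catalyze it.
Annotating the graph maps KO-level copy-number scores onto reactions by
averaging each KO over the selected samples and combining alternative
enzymes — by sum (default: alternative enzymes add to the reaction's
total gene dosage), mean, or max.

The on-disk format is a three-record TSV kept deliberately tiny:

    C   <compound id>   <label>
    R   <reaction id>   <label>   <ko1,ko2,...>
    E   <from id>       <to id>
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import numpy as np

from .scoring import ScoreTable

__all__ = ["ModuleGraphError", "read_module_graph", "write_module_graph", "annotate_module"]

COMBINERS = {"sum": sum, "mean": lambda v: sum(v) / len(v), "max": max}


class ModuleGraphError(ValueError):
    """Raised when a module graph file violates its format contract."""


def _validate(graph: nx.DiGraph) -> nx.DiGraph:
    for node, data in graph.nodes(data=True):
        if data.get("kind") == "reaction" and not data.get("kos"):
            raise ModuleGraphError(f"reaction {node!r} has an empty KO set")
    return graph


def read_module_graph(path: str | Path) -> nx.DiGraph:
    """Parse a module-graph TSV into a validated bipartite digraph.

    Nodes carry ``kind`` ('compound' or 'reaction'), ``label``, and — for
    reactions — ``kos`` (a frozen set of KO ids) plus a ``score`` slot
    left unset until :func:`annotate_module` fills it.
    """
    graph = nx.DiGraph()
    edges: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "C":
                if len(fields) != 3:
                    raise ModuleGraphError(f"line {lineno}: C records need 3 fields")
                _add_node(graph, fields[1], lineno, kind="compound", label=fields[2])
            elif kind == "R":
                if len(fields) != 4:
                    raise ModuleGraphError(f"line {lineno}: R records need 4 fields")
                kos = frozenset(k for k in fields[3].split(",") if k)
                if not kos:
                    raise ModuleGraphError(
                        f"line {lineno}: reaction {fields[1]!r} has an empty KO list"
                    )
                _add_node(
                    graph, fields[1], lineno, kind="reaction", label=fields[2], kos=kos, score=None
                )
            elif kind == "E":
                if len(fields) != 3:
                    raise ModuleGraphError(f"line {lineno}: E records need 3 fields")
                edges.append((fields[1], fields[2], lineno))
            else:
                raise ModuleGraphError(
                    f"line {lineno}: unknown record type {kind!r} (expected C, R, or E)"
                )
    for src, dst, lineno in edges:
        for endpoint in (src, dst):
            if endpoint not in graph:
                raise ModuleGraphError(
                    f"line {lineno}: edge references unknown node {endpoint!r}"
                )
        graph.add_edge(src, dst)
    return _validate(graph)


def _add_node(graph: nx.DiGraph, node_id: str, lineno: int, **attrs) -> None:
    if node_id in graph:
        raise ModuleGraphError(f"line {lineno}: duplicate node id {node_id!r}")
    graph.add_node(node_id, **attrs)


def write_module_graph(graph: nx.DiGraph, path: str | Path) -> None:
    """Serialize a module graph (with any annotation scores) back to TSV."""
    with open(path, "w") as fh:
        for node, data in graph.nodes(data=True):
            if data["kind"] == "compound":
                fh.write(f"C\t{node}\t{data['label']}\n")
            else:
                kos = ",".join(sorted(data["kos"]))
                fh.write(f"R\t{node}\t{data['label']}\t{kos}\n")
                if data.get("score") is not None:
                    fh.write(f"# score\t{node}\t{data['score']!r}\n")
        for src, dst in graph.edges:
            fh.write(f"E\t{src}\t{dst}\n")


def annotate_module(
    graph: nx.DiGraph,
    scores: ScoreTable,
    samples: list[str],
    combine: str = "sum",
) -> nx.DiGraph:
    """Set each reaction's score from the KO scores over selected samples.

    Each KO's score is its mean over the selected samples (undefined
    cells excluded); KOs absent from the score table contribute 0; the
    per-KO means are then combined with ``combine``.  A reaction whose
    KOs are all present but undefined in every selected sample is left
    unset, with a warning.  Topology is never modified; a copy of the
    graph is returned.
    """
    if scores.stratified:
        raise ValueError("annotate_module needs unstratified scores; aggregate taxa first")
    if not samples:
        raise ValueError("no samples selected")
    missing_samples = [s for s in samples if s not in scores.df.columns]
    if missing_samples:
        raise ValueError(f"samples not in score table: {missing_samples}")
    if combine not in COMBINERS:
        raise ValueError(f"combine must be one of {sorted(COMBINERS)}, got {combine!r}")

    annotated = graph.copy()
    for node, data in annotated.nodes(data=True):
        if data.get("kind") != "reaction":
            continue
        ko_means: list[float] = []
        for ko in sorted(data["kos"]):
            if ko not in scores.df.index:
                ko_means.append(0.0)
                continue
            cells = scores.df.loc[ko, samples].astype(float).dropna()
            if cells.empty:
                continue  # all selected cells undefined for this KO
            ko_means.append(float(cells.mean()))
        if not ko_means:
            warnings.warn(
                f"reaction {node!r}: all selected score cells undefined; score left unset",
                stacklevel=2,
            )
            data["score"] = None
            continue
        data["score"] = float(COMBINERS[combine](ko_means))
    return annotated
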