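"""Readers and writers for graphs, feature matrices and result tables.

All delimited output is tab-separated with ``repr``-round-trip float
precision and ``#``-prefixed metadata lines, so files diff cleanly.
"""

from __future__ import annotations

import os

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import WeightedGraph

__all__ = [
    "read_graph",
    "read_edge_list",
    "write_edge_list",
    "read_feature_matrix",
    "write_table",
    "read_table",
    "write_partition",
]


def read_graph(path, fmt=None, weight_mode="distance"):
    """Read a graph, auto-detecting the format from the extension.

    ``.graphml`` and ``.gml`` go through networkx; anything else is parsed
    as a delimited edge list (``u v [weight]``, ``#`` comments).
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {"": "edgelist", ".graphml": "graphml", ".gml": "gml"}.get(ext, "edgelist")
    if fmt == "graphml":
        return WeightedGraph.from_networkx(nx.Graph(nx.read_graphml(path)))
    if fmt == "gml":
        return WeightedGraph.from_networkx(nx.Graph(nx.read_gml(path, label="id")))
    if fmt == "edgelist":
        return read_edge_list(path)
    raise ValueError(f"unknown graph format {fmt!r}")


def read_edge_list(path, delimiter=None, comments="#"):
    """Parse a delimited edge list ``u v [weight]``.

    Node labels may be arbitrary strings; they are mapped to dense integer
    ids kept in ``WeightedGraph.node_ids``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(comments):
                continue
            parts = line.split(delimiter)
            if len(parts) < 2:
                raise ValueError(f"malformed edge-list line: {line!r}")
            u, v = parts[0], parts[1]
            w = float(parts[2]) if len(parts) > 2 else 1.0
            rows.append((u, v, w))
    labels = sorted({u for u, _, _ in rows} | {v for _, v, _ in rows},
                    key=lambda s: (len(s), s))
    index = {lbl: i for i, lbl in enumerate(labels)}
    edges, w = [], []
    seen = set()
    for u, v, wi in rows:
        i, j = index[u], index[v]
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        edges.append(key)
        w.append(wi)
    edges = np.array(edges, dtype=np.int64).reshape(-1, 2)
    w = np.array(w)
    ids = labels if any(str(i) != lbl for i, lbl in enumerate(labels)) else None
    return WeightedGraph(len(labels), edges, w, np.ones_like(w), node_ids=ids)


def write_edge_list(graph: WeightedGraph, path, header=None):
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# u\tv\tweight\n")
        for (u, v), wi in zip(graph.edges, graph.w):
            lu = graph.node_ids[u] if graph.node_ids else u
            lv = graph.node_ids[v] if graph.node_ids else v
            fh.write(f"{lu}\t{lv}\t{float(wi)!r}\n")


def read_feature_matrix(path, delimiter="\t"):
    """Read a binary entity-by-feature matrix.

    Expects a header row of feature names and a first column of entity
    names.  Returns ``(B, entity_names, feature_names)``.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    B = df.to_numpy()
    if not np.isin(B, (0, 1)).all():
        raise ValueError("feature matrix must contain only 0/1 entries")
    return B.astype(np.int8), list(df.index), list(df.columns)


def write_table(df: pd.DataFrame, path, metadata: dict | None = None):
    """Write a DataFrame as tab-separated text with ``#`` metadata lines."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def read_table(path):
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def write_partition(labels, path, node_ids=None, metadata: dict | None = None):
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# node\tcommunity\n")
        for i, c in enumerate(labels):
            name = node_ids[i] if node_ids else i
            fh.write(f"{name}\t{int(c)}\n")
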