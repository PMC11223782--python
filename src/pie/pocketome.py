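"""Pocketome minimum spanning tree over descriptor-space distances.

The pocketome is summarized as the exact MST of the complete graph whose
edge weights are the pairwise descriptor distances: the tree spans every
pocket while minimizing total distance, so locally similar pockets end
up adjacent. Because the Gaussian kernel is strictly decreasing, the
same edge set also maximizes total PSI; PSI is attached to each edge as
an attribute while the weight stays the raw distance.

Kruskal with an explicit (weight, min id, max id) edge order gives a
deterministic tree even with tied weights. networkx holds the graph and
handles GraphML export.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .similarity import DistanceMatrix

ANNOTATION_DESCRIPTORS = ["volume", "exposure", "frac_hydrophobic",
                          "frac_aromatic", "asphericity"]
ANNOTATION_ALIASES = {"frac_hydrophobic": "hydrophobicity",
                      "frac_aromatic": "aromaticity"}


@dataclass
class PocketomeTree:
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, data["distance"])
                for u, v, data in self.graph.edges(data=True)]

    @property
    def total_weight(self) -> float:
        return float(sum(d for _, _, d in self.edges))

    def is_valid_tree(self) -> bool:
        g = self.graph
        return (nx.is_connected(g)
                and g.number_of_edges() == g.number_of_nodes() - 1)


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(dm: DistanceMatrix,
                          psi_matrix: Optional[np.ndarray] = None,
                          ) -> PocketomeTree:
    """Exact MST of the complete pocket graph weighted by distance.

    Ties are resolved by sorting edges on (weight, min id, max id), so
    the tree is a pure function of the distance matrix.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two pockets for a spanning tree")
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((ids[i], ids[j]))
            edges.append((float(dm.d[i, j]), a, b, i, j))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))

    g = nx.Graph()
    g.add_nodes_from(ids)
    uf = _UnionFind(ids)
    taken = 0
    for w, a, b, i, j in edges:
        if uf.union(a, b):
            attrs = {"distance": w}
            if psi_matrix is not None:
                attrs["psi"] = float(psi_matrix[i, j])
            g.add_edge(a, b, **attrs)
            taken += 1
            if taken == n - 1:
                break
    return PocketomeTree(graph=g)


def annotate_nodes(tree: PocketomeTree, descriptors: pd.DataFrame,
                   metadata: Optional[pd.DataFrame] = None) -> PocketomeTree:
    """Attach raw (pre-standardization) descriptor annotations per node:
    volume, exposure, hydrophobicity, aromaticity, asphericity, plus
    class and family tags from an optional metadata table indexed by
    pocket id."""
    for node in tree.graph.nodes:
        if node not in descriptors.index:
            raise KeyError(f"no descriptor row for node {node!r}")
        row = descriptors.loc[node]
        attrs = {}
        for name in ANNOTATION_DESCRIPTORS:
            if name in row.index:
                attrs[ANNOTATION_ALIASES.get(name, name)] = float(row[name])
        if "pocket_class" in row.index:
            attrs["pocket_class"] = str(row["pocket_class"])
        if metadata is not None and node in metadata.index:
            meta_row = metadata.loc[node]
            for col in metadata.columns:
                val = meta_row[col]
                if pd.notna(val):
                    attrs[str(col)] = (float(val)
                                       if isinstance(val, (int, float,
                                                           np.floating))
                                       else str(val))
        if "family" not in attrs:
            attrs.setdefault("family", "")
        tree.graph.nodes[node].update(attrs)
    return tree


def export_graph(tree: PocketomeTree, fmt: str, path) -> None:
    """Write the tree as graphml, json (lossless round-trip) or edge_tsv."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(tree.graph, path)
    elif fmt == "json":
        payload = {
            "nodes": [{"id": n, **tree.graph.nodes[n]}
                      for n in sorted(tree.graph.nodes)],
            "edges": [{"source": u, "target": v, **data}
                      for u, v, data in sorted(tree.graph.edges(data=True))],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    elif fmt == "edge_tsv":
        lines = ["source\ttarget\tdistance"]
        for u, v, data in sorted(tree.graph.edges(data=True)):
            lines.append(f"{u}\t{v}\t{data['distance']:.10g}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_graph_json(path) -> PocketomeTree:
    """Read back a tree written by :func:`export_graph` with fmt='json'."""
    payload = json.loads(Path(path).read_text())
    g = nx.Graph()
    for node in payload["nodes"]:
        attrs = dict(node)
        g.add_node(attrs.pop("id"), **attrs)
    for edge in payload["edges"]:
        attrs = dict(edge)
        u, v = attrs.pop("source"), attrs.pop("target")
        g.add_edge(u, v, **attrs)
    return PocketomeTree(graph=g)
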