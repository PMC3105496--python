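"""Semantic networks of resources with median-based edge pruning.

Resources become nodes (with semantic class and corpus frequency as
attributes), positive pairwise similarities become weighted undirected
edges.  Pruning removes every edge whose weight falls strictly below the
global median edge weight, or strictly below the median incident weight of
either endpoint; both medians are computed once, on the pre-pruning
network.  Nodes left without edges are dropped.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .profile import ProfileMatrix, ResourceInfo, WeightedProfileMatrix
from .similarity import SimilarityMatrix

FORMATS = ("graphml", "sif", "tsv")


def build_network(
    sim: SimilarityMatrix,
    node_attrs: Mapping[str, ResourceInfo] | ProfileMatrix | WeightedProfileMatrix | None = None,
) -> nx.Graph:
    """Build the weighted undirected graph from a similarity matrix.

    One edge per unordered pair with similarity > 0; the edge weight is the
    similarity.  Node attributes (semantic_class, corpus_frequency) are
    copied from the profile index when provided.
    """
    attrs: dict[str, ResourceInfo] = {}
    if node_attrs is not None and not isinstance(node_attrs, Mapping):
        infos = node_attrs.resources
        keys = [r.canonical_key for r in infos]
        if len(set(keys)) == len(keys):
            attrs = dict(zip(keys, infos))
        else:
            attrs = {f"{r.canonical_key}|{r.semantic_class}": r for r in infos}
    elif node_attrs is not None:
        attrs = dict(node_attrs)

    g = nx.Graph()
    for label in sim.resources:
        g.add_node(label)
        if label in attrs:
            g.nodes[label]["semantic_class"] = attrs[label].semantic_class
            g.nodes[label]["corpus_frequency"] = attrs[label].corpus_frequency
    for i in range(sim.n):
        for j in range(i + 1, sim.n):
            w = float(sim.entries[i, j])
            if w > 0.0:
                g.add_edge(sim.resources[i], sim.resources[j], weight=w)
    return g


def prune_edges(net: nx.Graph) -> nx.Graph:
    """Median-prune a network (global AND both-endpoint node medians).

    An edge survives iff its weight is >= the global median of all
    pre-pruning edge weights and >= the median incident weight of each of
    its endpoints.  Removal is strict-below, so ties at the median survive
    and an all-equal-weight network is left intact.  Isolated nodes are
    dropped from the result.  Medians are not recomputed after removal.
    """
    out = net.copy()
    weights = [d["weight"] for _, _, d in net.edges(data=True)]
    if not weights:
        out.remove_nodes_from(list(nx.isolates(out)))
        return out
    global_median = float(np.median(weights))
    node_median = {
        n: float(np.median([net.edges[n, nb]["weight"] for nb in net.neighbors(n)]))
        for n in net.nodes
        if net.degree(n) > 0
    }
    to_drop = [
        (u, v)
        for u, v, d in net.edges(data=True)
        if d["weight"] < global_median
        or d["weight"] < node_median[u]
        or d["weight"] < node_median[v]
    ]
    out.remove_edges_from(to_drop)
    out.remove_nodes_from(list(nx.isolates(out)))
    return out


def export_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the network; graphml is lossless, sif/tsv are edge-centric."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "sif":
        lines = []
        for u, v, d in net.edges(data=True):
            lines.append(f"{u}\t{float(d['weight'])!r}\t{v}")
        for n in nx.isolates(net):
            lines.append(str(n))
        path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
    elif format == "tsv":
        lines = ["node1\tnode2\tweight"]
        for u, v, d in net.edges(data=True):
            lines.append(f"{u}\t{v}\t{float(d['weight'])!r}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown network format: {format!r} (expected one of {FORMATS})")


def read_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        for _, _, d in g.edges(data=True):
            d["weight"] = float(d["weight"])
        return g
    if format == "sif":
        g = nx.Graph()
        for line in path.read_text(encoding="utf-8").splitlines():
            parts = line.split("\t")
            if len(parts) == 3:
                g.add_edge(parts[0], parts[2], weight=float(parts[1]))
            elif len(parts) == 1 and parts[0]:
                g.add_node(parts[0])
        return g
    if format == "tsv":
        g = nx.Graph()
        for line in path.read_text(encoding="utf-8").splitlines()[1:]:
            if not line.strip():
                continue
            u, v, w = line.split("\t")
            g.add_edge(u, v, weight=float(w))
        return g
    raise ValueError(f"unknown network format: {format!r} (expected one of {FORMATS})")
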