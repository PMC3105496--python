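"""Ward hierarchical clustering of resources from similarity matrices.

Similarities are turned into dissimilarities d = 1 - sim and clustered with
Ward's minimum-variance agglomeration applied *directly* to that table via
the Lance-Williams update

    d(i∪j, k) = [(n_i+n_k) d(i,k) + (n_j+n_k) d(j,k) - n_k d(i,j)]
                / (n_i + n_j + n_k),

i.e. the classic "ward" behaviour of R's hclust on a raw dissimilarity
(no squaring, no Euclidean embedding assumed).  Merge ties are broken by
the lexicographically smallest pair of cluster indices, which makes the
merge order fully deterministic.  The resulting linkage is monotone
(Ward's coefficients admit no inversions), so the tree can be cut and
leaf-ordered with the standard scipy utilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .similarity import SimilarityMatrix


def to_distance(sim: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Dissimilarity table d = 1 - sim with an exact zero diagonal."""
    entries = sim.entries if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    if entries.min() < 0 or entries.max() > 1:
        raise ValueError("similarities must lie in [0, 1]")
    d = 1.0 - entries
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class Dendrogram:
    """Binary merge tree: scipy-format linkage matrix + leaf labels."""

    labels: list[str]
    linkage: np.ndarray  # (n-1, 4): child1, child2, height, size

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf sequence of the dendrogram (heatmap order)."""
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> dict[str, int]:
        """Flat partition into k clusters (labels -> 1..k)."""
        assignment = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assignment)}

    def to_newick(self) -> str:
        """Newick string; branch length = parent height - child height."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            if node.is_leaf():
                return f"{_newick_escape(self.labels[node.id])}:{parent_height:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.10g}"

        root = tree
        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def _newick_escape(label: str) -> str:
    if any(c in label for c in " ():,;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def ward_cluster(distances: np.ndarray | SimilarityMatrix, labels: Sequence[str] | None = None) -> Dendrogram:
    """Agglomerative Ward clustering of a dissimilarity table.

    Accepts a square dissimilarity array (with labels) or a
    SimilarityMatrix (converted via ``to_distance``).  Requires at least
    two items.
    """
    if isinstance(distances, SimilarityMatrix):
        labels = list(distances.resources)
        d = to_distance(distances)
    else:
        d = np.asarray(distances, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(d.shape[0])]
        labels = list(labels)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance table must be square")
    if n < 2:
        raise ValueError("clustering requires at least 2 resources")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance table must be symmetric")

    # active cluster bookkeeping; new clusters get ids n, n+1, ...
    dist: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        # smallest distance; ties -> lexicographically smallest (i, j)
        (i, j), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = n + step
        ni, nj = size[i], size[j]
        for k in sorted(active - {i, j}):
            nk = size[k]
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = ((ni + nk) * dik + (nj + nk) * djk - nk * h) / (ni + nj + nk)
            dist[(k, new)] = dnew
        for pair in [p for p in dist if i in p or j in p]:
            del dist[pair]
        active -= {i, j}
        active.add(new)
        size[new] = ni + nj
        Z[step] = [i, j, h, ni + nj]
    return Dendrogram(labels, Z)


def export_tree(dend: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(dend.to_newick() + "\n", encoding="utf-8")


def leaf_order(dend: Dendrogram) -> list[str]:
    return dend.leaf_order()


def export_leaf_ordered_matrix(sim: SimilarityMatrix, dend: Dendrogram, path: str | Path) -> None:
    """Write the similarity matrix with rows/columns permuted to leaf order."""
    order = dend.leaf_order()
    idx = [sim.resources.index(r) for r in order]
    sub = sim.entries[np.ix_(idx, idx)]
    pd.DataFrame(sub, index=order, columns=order).to_csv(path)
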