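"""Agglomerative clustering for dendrograms and Newick export.

``complete`` linkage is used to validate MLG collapsing visually (the
rectangles drawn at the threshold height enclose exactly the MLGs), and
``ward_d2`` to display collection-wide structure.  Heights are on the
distance scale in both cases.  The Newick rendering is ultrametric:
leaves sit at height 0 and each branch length is the difference between
parent and child merge heights.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.cluster import hierarchy

from .io import DistanceMatrix

__all__ = ["Dendrogram", "hierarchical_cluster", "to_newick"]

_METHODS = {"complete": "complete", "ward_d2": "ward"}

# characters that force quoting of a Newick label
_NEWICK_RESERVED = set("(),:;'[] \t\n")


@dataclasses.dataclass
class Dendrogram:
    """A binary merge tree over samples (scipy linkage encoding).

    Row k of ``merges`` joins nodes ``i`` and ``j`` (leaves are 0..n-1,
    internal nodes n+k) at ``heights[k]``.
    """

    labels: list[str]
    merges: np.ndarray  # (n-1, 2) int
    heights: np.ndarray  # (n-1,)
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, height: float, strict: bool = True) -> dict[str, str]:
        """Partition by keeping merges below ``height``.

        With ``strict=True`` a merge at exactly ``height`` is *not*
        kept, matching the strict-below MLG merge semantics.  Returns
        sample_id -> group id (smallest member label).
        """
        n = self.n_leaves
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for k, (i, j) in enumerate(self.merges):
            h = self.heights[k]
            if (h < height) if strict else (h <= height):
                node = n + k
                parent[find(int(i))] = node
                parent[find(int(j))] = node
        roots: dict[int, list[str]] = {}
        for leaf in range(n):
            roots.setdefault(find(leaf), []).append(self.labels[leaf])
        return {s: min(ms) for ms in roots.values() for s in ms}


def hierarchical_cluster(dm: DistanceMatrix, method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    ``ward_d2`` applies the Ward update on squared distances with heights
    reported on the distance scale (scipy's ``ward`` on a precomputed
    condensed matrix).  Samples are clustered in lexicographic order so
    ties resolve toward the smallest leaf label.
    """
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}, got {method!r}")
    if dm.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    if not np.isfinite(dm.values).all():
        raise ValueError("non-finite distances cannot be clustered")
    order = sorted(range(dm.n_samples), key=lambda i: dm.sample_ids[i])
    sub = dm.subset([dm.sample_ids[i] for i in order])
    Z = hierarchy.linkage(sub.condensed(), method=_METHODS[method])
    return Dendrogram(
        labels=list(sub.sample_ids),
        merges=Z[:, :2].astype(int),
        heights=Z[:, 2].astype(float),
        method=method,
    )


def _quote(label: str) -> str:
    if any(c in _NEWICK_RESERVED for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(d: Dendrogram) -> str:
    """Render the dendrogram as a Newick string (terminated with ';').

    Children of each internal node are ordered by their smallest leaf
    label, keeping the output stable.
    """
    n = d.n_leaves
    height = {i: 0.0 for i in range(n)}
    minleaf = {i: d.labels[i] for i in range(n)}
    text: dict[int, str] = {}
    for i in range(n):
        text[i] = _quote(d.labels[i])
    for k, (i, j) in enumerate(d.merges):
        i, j = int(i), int(j)
        node = n + k
        h = float(d.heights[k])
        children = sorted((i, j), key=lambda c: minleaf[c])
        parts = [f"{text[c]}:{_fmt(h - height[c])}" for c in children]
        text[node] = "(" + ",".join(parts) + ")"
        height[node] = h
        minleaf[node] = min(minleaf[i], minleaf[j])
    root = 2 * n - 2
    return text[root] + ";"


def _fmt(x: float) -> str:
    return f"{x:.10g}"
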