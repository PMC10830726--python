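"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as naive per-pair / per-merge
loops, independent of the vectorized or Lance-Williams code paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def ibs_pair(a: np.ndarray, b: np.ndarray) -> float:
    """IBS distance between two dosage vectors, naive loop."""
    shared = 0.0
    n_valid = 0
    for ga, gb in zip(a, b):
        if np.isnan(ga) or np.isnan(gb):
            continue
        n_valid += 1
        shared += 2 - abs(ga - gb)
    if n_valid == 0:
        return 1.0
    return 1.0 - shared / (2.0 * n_valid)


def jaccard_pair(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard distance between two presence vectors, naive loop."""
    n11 = n10 = n01 = 0
    for xa, xb in zip(a, b):
        if np.isnan(xa) or np.isnan(xb):
            continue
        if xa == 1 and xb == 1:
            n11 += 1
        elif xa == 1:
            n10 += 1
        elif xb == 1:
            n01 += 1
    denom = n11 + n10 + n01
    if denom == 0:
        return 0.0
    return (n10 + n01) / denom


def pairwise(values: np.ndarray, pair_fn) -> np.ndarray:
    """Full pairwise matrix from a per-pair function (columns = samples)."""
    n = values.shape[1]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pair_fn(values[:, i], values[:, j])
    return out


def connected_components(dist: np.ndarray, labels: list[str], t: float):
    """Union-find components of the graph with edges d < t (strict)."""
    parent = list(range(len(labels)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] < t:
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(labels[i])
    return frozenset(frozenset(g) for g in groups.values())


def agglomerate(dist: np.ndarray, labels: list[str], t: float, linkage: str):
    """Naive merge-while-below agglomeration recomputing cluster linkage
    from the original matrix at every step."""
    clusters: list[set[int]] = [{i} for i in range(len(labels))]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            cross = [dist[i, j] for i in clusters[a] for j in clusters[b]]
            if linkage == "nearest":
                d = min(cross)
            elif linkage == "farthest":
                d = max(cross)
            else:
                d = sum(cross) / len(cross)
            key = (d, min(min(labels[i] for i in clusters[a]),
                          min(labels[j] for j in clusters[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        if not d < t:
            break
        clusters[a] |= clusters[b]
        del clusters[b]
    return frozenset(frozenset(labels[i] for i in c) for c in clusters)


def complete_linkage_merge_heights(dist: np.ndarray):
    """Brute-force complete-linkage agglomeration returning sorted merge
    heights (each the maximum cross-pair distance at that merge)."""
    n = dist.shape[0]
    clusters: list[set[int]] = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] |= clusters[b]
        del clusters[b]
    return sorted(heights)


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random symmetric zero-diagonal matrix with entries in [0, 1]."""
    m = rng.random((n, n))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


def ward_d2_heights(dist: np.ndarray):
    """Independent Lance-Williams ward.D2 heights (distance scale)."""
    n = dist.shape[0]
    d2 = dist.astype(float) ** 2
    active = list(range(n))
    size = {i: 1 for i in range(n)}
    work = d2.copy()
    np.fill_diagonal(work, np.inf)
    heights = []
    while len(active) > 1:
        sub = [(work[a, b], a, b) for ai, a in enumerate(active) for b in active[ai + 1:]]
        d, i, j = min(sub)
        heights.append(np.sqrt(d))
        for k in active:
            if k in (i, j):
                continue
            ni, nj, nk = size[i], size[j], size[k]
            new = ((ni + nk) * work[i, k] + (nj + nk) * work[j, k] - nk * d) / (
                ni + nj + nk
            )
            work[i, k] = work[k, i] = new
        size[i] += size.pop(j)
        active.remove(j)
    return heights
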