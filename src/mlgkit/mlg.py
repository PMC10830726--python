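"""Multilocus-genotype (MLG) collapsing at a genetic-distance threshold.

Samples whose pairwise distances fall *strictly below* a threshold are
merged into one MLG by agglomerative clustering: repeatedly merge the
pair of current clusters with the smallest linkage distance while that
distance is below the threshold.  The linkage distance between clusters
is the minimum (``nearest``), mean (``average``) or maximum
(``farthest``) of the cross-pair distances.

``nearest`` is the default.  It is equivalent to connected components of
the graph with edges ``d < t`` and allows chaining: a large redundancy
group may contain accession pairs whose distance exceeds the threshold,
which is exactly what large genebank MLG clusters look like in practice
(their internal distance dispersion reaches above the threshold).
``farthest`` is the conservative alternative — every pair inside a
reported MLG is below the threshold — and matches cutting a
complete-linkage dendrogram at the threshold height, which is how MLGs
are validated visually.  The linkage used is recorded on the partition
and surfaced in every report.

Determinism: among tied candidate merges the pair whose (sorted) smallest
member sample ids are lexicographically smallest is merged first, and MLG
ids are the smallest member sample id, so outputs are stable across runs.

Degenerate (flagged) distance entries are treated as non-mergeable and
reported; they never justify a merge.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .io import DistanceMatrix

__all__ = [
    "MLGPartition",
    "PartitionSummary",
    "SweepResult",
    "collapse_mlg",
    "summarize_partition",
    "summarize_sizes",
    "threshold_sweep",
    "round_half_up",
]

LINKAGES = ("nearest", "average", "farthest")


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.005 -> 0.01 at 2 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass
class MLGPartition:
    """Assignment of samples to MLGs at a stated threshold and linkage."""

    assignment: dict[str, str]  # sample_id -> mlg_id (smallest member id)
    threshold: float
    linkage: str
    metric: str
    excluded_pairs: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.assignment.items():
            out.setdefault(g, []).append(s)
        return {g: sorted(ms) for g, ms in sorted(out.items())}

    def sizes(self) -> dict[int, int]:
        """Size distribution: MLG size -> number of MLGs of that size."""
        counts = Counter(self.assignment.values())
        return dict(sorted(Counter(counts.values()).items()))

    @property
    def n_mlgs(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def n_samples(self) -> int:
        return len(self.assignment)

    def as_frozen(self) -> frozenset[frozenset[str]]:
        """Label-free view for comparing partitions up to relabeling."""
        return frozenset(frozenset(ms) for ms in self.groups().values())


def collapse_mlg(
    dm: DistanceMatrix, threshold: float, linkage: str = "nearest"
) -> MLGPartition:
    """Collapse samples into MLGs; merging requires distance < threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    n = dm.n_samples
    labels = list(dm.sample_ids)
    work = dm.values.astype(float).copy()
    # flagged sentinel entries must never drive a merge
    pos = {s: i for i, s in enumerate(labels)}
    for a, b in dm.degenerate_pairs:
        work[pos[a], pos[b]] = work[pos[b], pos[a]] = np.inf
    np.fill_diagonal(work, np.inf)

    active = list(range(n))
    members: dict[int, list[str]] = {i: [labels[i]] for i in range(n)}
    size = {i: 1 for i in range(n)}
    smallest = {i: labels[i] for i in range(n)}  # lexicographic cluster key

    while len(active) > 1:
        sub = work[np.ix_(active, active)]
        d = sub.min()
        if not d < threshold:
            break
        # tie-break: lexicographically smallest (minor, major) member-id key
        best = None
        ii, jj = np.nonzero(sub == d)
        for a_, b_ in zip(ii, jj):
            if a_ >= b_:
                continue
            ci, cj = active[a_], active[b_]
            key = tuple(sorted((smallest[ci], smallest[cj])))
            if best is None or key < best[0]:
                best = (key, ci, cj)
        assert best is not None
        _, ci, cj = best
        # Lance-Williams update of cluster ci (absorbs cj)
        for ck in active:
            if ck in (ci, cj):
                continue
            dik, djk = work[ci, ck], work[cj, ck]
            if linkage == "nearest":
                new = min(dik, djk)
            elif linkage == "farthest":
                new = max(dik, djk)
            else:  # average: size-weighted mean of cross-pair distances
                new = (size[ci] * dik + size[cj] * djk) / (size[ci] + size[cj])
            work[ci, ck] = work[ck, ci] = new
        members[ci].extend(members.pop(cj))
        size[ci] += size.pop(cj)
        smallest[ci] = min(smallest[ci], smallest[cj])
        active.remove(cj)
        work[cj, :] = np.inf
        work[:, cj] = np.inf

    assignment: dict[str, str] = {}
    for ci in active:
        gid = smallest[ci]
        for s in members[ci]:
            assignment[s] = gid
    return MLGPartition(
        assignment=assignment,
        threshold=threshold,
        linkage=linkage,
        metric=dm.metric,
        excluded_pairs=list(dm.degenerate_pairs),
    )


@dataclasses.dataclass
class PartitionSummary:
    """Collection-level distinctness/redundancy bookkeeping for a partition.

    ``n_units`` counts the clustered units (accessions); ``n_redundant``
    is ``n_units - n_mlgs``, i.e. the accessions beyond the first in each
    MLG.  Percentages are half-up rounded to 2 decimals, both computed
    from the same unrounded ratio.
    """

    n_mlgs: int
    n_units: int
    n_redundant: int
    pct_distinct: float
    pct_redundant: float
    size_distribution: dict[int, int]

    def to_dict(self) -> dict:
        return {
            "n_mlgs": self.n_mlgs,
            "n_units": self.n_units,
            "n_redundant": self.n_redundant,
            "pct_distinct": self.pct_distinct,
            "pct_redundant": self.pct_redundant,
            "size_distribution": {f"C{k}": v for k, v in self.size_distribution.items()},
        }


def summarize_sizes(sizes: Mapping[int, int]) -> PartitionSummary:
    """Summary from a size distribution {MLG size: number of MLGs}."""
    if not sizes:
        raise ValueError("empty partition")
    if any(s < 1 or c < 0 for s, c in sizes.items()):
        raise ValueError("sizes must be >= 1 with non-negative counts")
    n_mlgs = sum(sizes.values())
    n_units = sum(s * c for s, c in sizes.items())
    n_red = n_units - n_mlgs
    return PartitionSummary(
        n_mlgs=n_mlgs,
        n_units=n_units,
        n_redundant=n_red,
        pct_distinct=round_half_up(100.0 * n_mlgs / n_units, 2),
        pct_redundant=round_half_up(100.0 * n_red / n_units, 2),
        size_distribution=dict(sorted(sizes.items())),
    )


def summarize_partition(p: MLGPartition | Mapping[int, int]) -> PartitionSummary:
    """Summary of an :class:`MLGPartition` (or a raw size distribution)."""
    if isinstance(p, MLGPartition):
        if not p.assignment:
            raise ValueError("empty partition")
        return summarize_sizes(p.sizes())
    return summarize_sizes(p)


@dataclasses.dataclass
class SweepResult:
    """One collapse per threshold: (threshold, #MLGs, #singletons, #redundant)."""

    linkage: str
    metric: str
    rows: list[tuple[float, int, int, int]]

    def n_mlgs(self) -> list[int]:
        return [r[1] for r in self.rows]

    def to_dict(self) -> dict:
        return {
            "linkage": self.linkage,
            "metric": self.metric,
            "columns": ["threshold", "n_mlgs", "n_single", "n_redundant"],
            "rows": [list(r) for r in self.rows],
        }


def threshold_sweep(
    dm: DistanceMatrix, thresholds: Sequence[float], linkage: str = "nearest"
) -> SweepResult:
    """Collapse at each threshold (must be sorted ascending)."""
    ts = list(thresholds)
    if ts != sorted(ts):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in ts:
        p = collapse_mlg(dm, t, linkage)
        sizes = p.sizes()
        n_single = sizes.get(1, 0)
        rows.append((float(t), p.n_mlgs, n_single, p.n_samples - p.n_mlgs))
    return SweepResult(linkage=linkage, metric=dm.metric, rows=rows)
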