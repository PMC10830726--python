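"""Replicate-based calibration of the minimum genetic-distance threshold.

Technical and biological replicates of the same accession should be
genetically identical; whatever distance separates them is measurement
error.  The distinctness threshold is therefore proposed as the smallest
grid multiple strictly greater than the largest observed replicate-pair
distance (grid step 0.005 by default), so every replicate pair merges at
the proposal.  The rule reproduces the two canonical choices: a pooled
maximum of 0.0576 proposes 0.06, and 0.0127 proposes 0.015.

The proposal is a *starting point*, not an oracle: the result always
carries the per-class statistics (DNA-, extract- and individual-level
replicates) so a curator can override it.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import defaultdict
from typing import Sequence

import numpy as np

from .io import DistanceMatrix, SampleMeta
from .mlg import MLGPartition

__all__ = [
    "ReplicatePair",
    "ClassStats",
    "CalibrationResult",
    "enumerate_replicate_pairs",
    "calibrate_threshold",
    "validate_replicate_collapse",
    "ReplicateValidation",
]

PAIR_CLASSES = ("dna", "extract", "ind")


@dataclasses.dataclass(frozen=True)
class ReplicatePair:
    sample_a: str
    sample_b: str
    replicate_class: str

    def __post_init__(self) -> None:
        if self.replicate_class not in PAIR_CLASSES:
            raise ValueError(f"bad replicate class {self.replicate_class!r}")
        if self.sample_a == self.sample_b:
            raise ValueError("pair members must differ")


def enumerate_replicate_pairs(metas: Sequence[SampleMeta]) -> list[ReplicatePair]:
    """All unordered within-group pairs, tagged with the group's class.

    A group of k samples yields k(k-1)/2 pairs (trios give 3).  Groups
    with a single member produce a warning and no pairs.
    """
    groups: dict[str, list[SampleMeta]] = defaultdict(list)
    for m in metas:
        if m.replicate_class != "none" and m.replicate_group:
            groups[m.replicate_group].append(m)
    pairs: list[ReplicatePair] = []
    for gid in sorted(groups):
        ms = sorted(groups[gid], key=lambda m: m.sample_id)
        if len(ms) == 1:
            warnings.warn(f"replicate group {gid!r} has a single member; no pairs")
            continue
        classes = {m.replicate_class for m in ms}
        if len(classes) != 1:
            raise ValueError(f"replicate group {gid!r} mixes classes {sorted(classes)}")
        accs = {m.accession_id for m in ms}
        if len(accs) != 1:
            warnings.warn(
                f"replicate group {gid!r} spans accessions {sorted(accs)} "
                f"(possible tracking error)"
            )
        cls = classes.pop()
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                pairs.append(ReplicatePair(ms[i].sample_id, ms[j].sample_id, cls))
    return pairs


@dataclasses.dataclass
class ClassStats:
    n_pairs: int
    mean: float
    sd: float
    min: float
    max: float


@dataclasses.dataclass
class CalibrationResult:
    per_class: dict[str, ClassStats]
    pooled_max: float
    grid: float
    proposed_threshold: float

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: dataclasses.asdict(s) for c, s in self.per_class.items()
            },
            "pooled_max": self.pooled_max,
            "grid": self.grid,
            "proposed_threshold": self.proposed_threshold,
        }


def propose_threshold(pooled_max: float, grid: float = 0.005) -> float:
    """Smallest grid multiple strictly greater than ``pooled_max``."""
    if grid <= 0:
        raise ValueError("grid step must be positive")
    # the epsilon absorbs float drift when pooled_max sits on a grid line
    k = int(np.floor(pooled_max / grid + 1e-9)) + 1
    return round(k * grid, 12)


def calibrate_threshold(
    dm: DistanceMatrix, pairs: Sequence[ReplicatePair], grid: float = 0.005
) -> CalibrationResult:
    """Replicate-pair distance statistics and the grid-round-up proposal."""
    if not pairs:
        raise ValueError("no replicate pairs: calibration impossible")
    by_class: dict[str, list[float]] = defaultdict(list)
    for p in pairs:
        by_class[p.replicate_class].append(dm.loc(p.sample_a, p.sample_b))
    per_class = {}
    for cls in PAIR_CLASSES:
        ds = np.asarray(by_class.get(cls, []), dtype=float)
        if ds.size == 0:
            continue
        per_class[cls] = ClassStats(
            n_pairs=int(ds.size),
            mean=float(ds.mean()),
            sd=float(ds.std(ddof=1)) if ds.size > 1 else 0.0,
            min=float(ds.min()),
            max=float(ds.max()),
        )
    pooled_max = max(s.max for s in per_class.values())
    return CalibrationResult(
        per_class=per_class,
        pooled_max=pooled_max,
        grid=grid,
        proposed_threshold=propose_threshold(pooled_max, grid),
    )


@dataclasses.dataclass
class ReplicateValidation:
    """Did every accession's replicate samples land in a single MLG?

    ``failures`` lists accessions split across MLGs with the split sizes
    (e.g. ``"1+6"``).  ``cross_accession_merges`` lists MLGs that join
    samples of several accessions — genuine redundancy candidates, not
    failures.
    """

    failures: list[tuple[str, str]]
    cross_accession_merges: list[tuple[str, tuple[str, ...]]]

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "failures": [{"accession": a, "split": s} for a, s in self.failures],
            "cross_accession_merges": [
                {"mlg": g, "accessions": list(accs)}
                for g, accs in self.cross_accession_merges
            ],
        }


def validate_replicate_collapse(
    partition: MLGPartition, metas: Sequence[SampleMeta]
) -> ReplicateValidation:
    """Check that all samples of each replicated accession share one MLG."""
    acc_samples: dict[str, list[str]] = defaultdict(list)
    for m in metas:
        if m.sample_id in partition.assignment:
            acc_samples[m.accession_id].append(m.sample_id)
    failures = []
    for acc in sorted(acc_samples):
        samples = acc_samples[acc]
        if len(samples) < 2:
            continue
        mlgs = defaultdict(int)
        for s in samples:
            mlgs[partition.assignment[s]] += 1
        if len(mlgs) > 1:
            split = "+".join(str(c) for c in sorted(mlgs.values()))
            failures.append((acc, split))
    sample_acc = {m.sample_id: m.accession_id for m in metas}
    merges = []
    for gid, members in partition.groups().items():
        accs = sorted({sample_acc.get(s, s) for s in members})
        if len(accs) > 1:
            merges.append((gid, tuple(accs)))
    return ReplicateValidation(failures=failures, cross_accession_merges=merges)
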