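"""Per-marker statistics and ordered quality-filter cascades.

Marker selection proceeds as an ordered cascade of threshold filters: a
marker excluded at stage k is not reconsidered downstream, and the report
records the surviving count after every stage (the familiar F0, F1, ...
bookkeeping).  The final survivor set equals the intersection of the
single-filter survivor sets; the order matters only for the per-stage
counts.

Matrix-derived statistics (maf, call_rate, one_ratio) are recomputed from
the current matrix whenever the sample set changes; the depth and
reproducibility statistics come from marker metadata and are fixed inputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import MarkerMatrix

__all__ = [
    "FilterCascade",
    "CascadeStage",
    "CascadeReport",
    "compute_marker_stats",
    "apply_cascade",
    "SNP_DEFAULT_CASCADE",
    "SILICO_DEFAULT_CASCADE",
]

_COMPARATORS = {
    ">=": lambda s, t: s >= t,
    "<=": lambda s, t: s <= t,
    "==": lambda s, t: s == t,
}

#: statistics available per marker type (matrix-derived + metadata)
_STATS_BY_TYPE = {
    "snp": {"maf", "call_rate", "avg_marker_count", "cv_marker_count", "rep_avg", "mapped"},
    "silico": {
        "call_rate",
        "one_ratio",
        "avg_read_depth",
        "cv_read_depth",
        "reproducibility",
        "mapped",
    },
}


@dataclasses.dataclass(frozen=True)
class FilterCascade:
    """An ordered list of ``(statistic, comparator, threshold)`` stages."""

    marker_type: str
    stages: tuple[tuple[str, str, object], ...]

    def __post_init__(self) -> None:
        known = _STATS_BY_TYPE.get(self.marker_type)
        if known is None:
            raise ValueError(f"unknown marker_type {self.marker_type!r}")
        for stat, op, _ in self.stages:
            if stat not in known:
                raise ValueError(
                    f"statistic {stat!r} is not defined for {self.marker_type} markers"
                )
            if op not in _COMPARATORS:
                raise ValueError(f"unknown comparator {op!r} (use >=, <= or ==)")


# thresholds are inclusive exactly as printed; boundary markers are retained
SNP_DEFAULT_CASCADE = FilterCascade(
    "snp",
    (
        ("maf", ">=", 0.001),
        ("call_rate", ">=", 0.8),
        ("avg_marker_count", ">=", 12),
        ("cv_marker_count", "<=", 0.6),
        ("rep_avg", ">=", 0.98),
        ("mapped", "==", True),
    ),
)

SILICO_DEFAULT_CASCADE = FilterCascade(
    "silico",
    (
        ("call_rate", ">=", 0.95),
        ("one_ratio", ">=", 0.05),
        ("avg_read_depth", ">=", 12),
        ("cv_read_depth", "<=", 0.7),
        ("reproducibility", ">=", 0.98),
    ),
)


def default_cascade(marker_type: str) -> FilterCascade:
    return SNP_DEFAULT_CASCADE if marker_type == "snp" else SILICO_DEFAULT_CASCADE


def compute_marker_stats(m: MarkerMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Matrix-derived marker statistics merged with metadata.

    Returns a DataFrame indexed by marker_id with ``call_rate`` plus
    ``maf`` (snp) or ``one_ratio`` (silico), the metadata columns passed
    through unchanged, and a ``no_calls`` flag for markers with zero
    called samples (their maf/one_ratio is reported as 0; such markers
    fail any call-rate filter anyway).
    """
    missing = [mk for mk in m.marker_ids if mk not in meta.index]
    if missing:
        raise ValueError(
            f"marker metadata does not cover {len(missing)} markers "
            f"(first: {missing[0]!r})"
        )
    called = ~np.isnan(m.values)
    n_called = called.sum(axis=1)
    no_calls = n_called == 0
    stats = pd.DataFrame(index=pd.Index(m.marker_ids, name="marker_id"))
    stats["call_rate"] = n_called / m.n_samples
    safe = np.maximum(n_called, 1)
    if m.marker_type == "snp":
        p = np.nansum(m.values, axis=1) / (2.0 * safe)
        stats["maf"] = np.where(no_calls, 0.0, np.minimum(p, 1.0 - p))
    else:
        ones = np.nansum(m.values, axis=1)
        stats["one_ratio"] = np.where(no_calls, 0.0, ones / safe)
    stats["no_calls"] = no_calls
    passthrough = meta.loc[m.marker_ids]
    for c in passthrough.columns:
        stats[c] = passthrough[c].to_numpy()
    return stats


@dataclasses.dataclass
class CascadeStage:
    name: str
    statistic: str
    comparator: str
    threshold: object
    n_surviving: int
    excluded: list[str]


@dataclasses.dataclass
class CascadeReport:
    """Per-stage survivor counts and the final marker list for one cascade."""

    marker_type: str
    n_input: int
    stages: list[CascadeStage]
    final_ids: list[str]

    def stage_counts(self) -> list[int]:
        """Survivor counts including the unfiltered F0 stage."""
        return [self.n_input] + [s.n_surviving for s in self.stages]

    def to_dict(self) -> dict:
        return {
            "marker_type": self.marker_type,
            "n_input": self.n_input,
            "stages": [
                {
                    "name": s.name,
                    "statistic": s.statistic,
                    "comparator": s.comparator,
                    "threshold": s.threshold,
                    "n_surviving": s.n_surviving,
                }
                for s in self.stages
            ],
            "final_ids": self.final_ids,
        }


def apply_cascade(
    stats: pd.DataFrame, cascade: FilterCascade, keep_excluded_ids: bool = True
) -> CascadeReport:
    """Apply the cascade stages in order; excluded markers never return."""
    for stat, _, _ in cascade.stages:
        if stat not in stats.columns:
            raise ValueError(f"statistic {stat!r} missing from marker stats table")
    surviving = stats
    stages: list[CascadeStage] = []
    for k, (stat, op, thr) in enumerate(cascade.stages, start=1):
        col = surviving[stat]
        keep = _COMPARATORS[op](col, thr)
        keep = keep.fillna(False) if keep.dtype == object else keep & col.notna()
        excluded = list(surviving.index[~keep]) if keep_excluded_ids else []
        surviving = surviving[keep]
        stages.append(
            CascadeStage(
                name=f"F{k}",
                statistic=stat,
                comparator=op,
                threshold=thr,
                n_surviving=len(surviving),
                excluded=excluded,
            )
        )
    return CascadeReport(
        marker_type=cascade.marker_type,
        n_input=len(stats),
        stages=stages,
        final_ids=list(surviving.index),
    )
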