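"""Per-sample statistics and low-quality sample flagging.

Each rule is a *keep interval* on one statistic: a sample is kept when
``lower < value < upper`` (either bound optional, both strict), so
"below or above" exclusions are expressible with one rule.  A sample is
excluded when it fails at least ``min_failures`` rules (default 1).

Observed heterozygosity (Ho) is a contamination screen: unintended DNA
mixtures raise heterozygous calls, while very low Ho (like very low call
rates or tag counts) signals degraded DNA.  The library-quality category
(``target_qc``) is reported but never auto-excludes — the numeric rules
decide.

Note on the silico call-rate rule: this package ships it *disabled*.
The upstream keep-direction for individual silico call rate is
internally inconsistent with the cohort it describes (a keep-rule
``> 0.996`` would discard nearly all samples when the cohort mean is
0.97), so no default is claimed; configure the rule explicitly if your
data support one.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import MarkerMatrix, SampleMeta, sample_meta_frame

__all__ = [
    "SampleFilterRule",
    "SampleQCReport",
    "compute_sample_stats",
    "flag_samples",
    "DEFAULT_SAMPLE_RULES",
]


@dataclasses.dataclass(frozen=True)
class SampleFilterRule:
    """Keep-interval rule: keep samples with ``lower < statistic < upper``."""

    statistic: str
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.lower is None and self.upper is None:
            raise ValueError(f"rule on {self.statistic!r} has no bounds")
        if self.lower is not None and self.upper is not None and self.lower >= self.upper:
            raise ValueError(f"rule on {self.statistic!r}: lower must be < upper")

    def passes(self, value: float) -> bool:
        if np.isnan(value):
            return False  # undefined statistic cannot demonstrate quality
        if self.lower is not None and value <= self.lower:
            return False
        if self.upper is not None and value >= self.upper:
            return False
        return True

    @property
    def label(self) -> str:
        lo = "-inf" if self.lower is None else f"{self.lower:g}"
        hi = "+inf" if self.upper is None else f"{self.upper:g}"
        return f"{self.statistic} in ({lo}, {hi})"


DEFAULT_SAMPLE_RULES: tuple[SampleFilterRule, ...] = (
    SampleFilterRule("tagcount_total", lower=1_500_000),
    SampleFilterRule("tagcount_unique", lower=230_000),
    SampleFilterRule("snp_call_rate", lower=0.73),
    SampleFilterRule("ho", lower=0.05, upper=0.16),
    SampleFilterRule("silico_one_ratio", lower=0.2),
)


def compute_sample_stats(
    snp: MarkerMatrix | None,
    silico: MarkerMatrix | None,
    metas: list[SampleMeta],
) -> pd.DataFrame:
    """Per-sample call rates, Ho, silico one-ratio and metadata counts.

    Either matrix may be ``None``; the corresponding statistics are NaN.
    Ho counts dosage-1 calls among a sample's non-missing SNP calls; a
    sample with zero SNP calls gets NaN Ho and a ``ho_undefined`` flag.
    """
    if snp is None and silico is None:
        raise ValueError("need at least one marker matrix")
    ref = snp if snp is not None else silico
    sample_ids = list(ref.sample_ids)
    if snp is not None and silico is not None and set(snp.sample_ids) != set(
        silico.sample_ids
    ):
        raise ValueError("snp and silico matrices must share the sample set")
    stats = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    stats["snp_call_rate"] = np.nan
    stats["ho"] = np.nan
    stats["silico_call_rate"] = np.nan
    stats["silico_one_ratio"] = np.nan
    stats["ho_undefined"] = False
    if snp is not None:
        called = ~np.isnan(snp.values)
        n_called = called.sum(axis=0)
        stats.loc[snp.sample_ids, "snp_call_rate"] = n_called / snp.n_markers
        het = (snp.values == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(n_called > 0, het / np.maximum(n_called, 1), np.nan)
        stats.loc[snp.sample_ids, "ho"] = ho
        stats.loc[snp.sample_ids, "ho_undefined"] = n_called == 0
    if silico is not None:
        called = ~np.isnan(silico.values)
        n_called = called.sum(axis=0)
        stats.loc[silico.sample_ids, "silico_call_rate"] = n_called / silico.n_markers
        ones = np.nansum(silico.values, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            one_ratio = np.where(n_called > 0, ones / np.maximum(n_called, 1), np.nan)
        stats.loc[silico.sample_ids, "silico_one_ratio"] = one_ratio
    mf = sample_meta_frame(metas)
    missing = [s for s in sample_ids if s not in mf.index]
    if missing:
        raise ValueError(f"sample metadata missing for {missing[:5]} ...")
    mf = mf.loc[sample_ids]
    stats["tagcount_total"] = mf["tagcount_total"].astype(float)
    stats["tagcount_unique"] = mf["tagcount_unique"].astype(float)
    stats["target_qc"] = mf["target_qc"]
    return stats


@dataclasses.dataclass
class SampleQCReport:
    """Pass/fail per rule per sample, failure counts and the excluded list."""

    rules: list[SampleFilterRule]
    failures: pd.DataFrame  # bool, samples x rule labels; True = failed
    n_failed: pd.Series
    excluded: list[str]
    min_failures: int = 1

    def to_dict(self) -> dict:
        return {
            "rules": [r.label for r in self.rules],
            "min_failures": self.min_failures,
            "n_excluded": len(self.excluded),
            "excluded": self.excluded,
            "failures_per_rule": {
                label: int(col.sum()) for label, col in self.failures.items()
            },
            "per_sample_failure_count": {
                s: int(c) for s, c in self.n_failed.items() if c > 0
            },
        }


def flag_samples(
    stats: pd.DataFrame,
    rules: tuple[SampleFilterRule, ...] = DEFAULT_SAMPLE_RULES,
    min_failures: int = 1,
) -> SampleQCReport:
    """Evaluate every rule on every sample; always produces a report."""
    for r in rules:
        if r.statistic not in stats.columns:
            raise ValueError(f"rule references unknown statistic {r.statistic!r}")
    failures = pd.DataFrame(index=stats.index)
    for r in rules:
        failures[r.label] = [not r.passes(v) for v in stats[r.statistic].astype(float)]
    n_failed = failures.sum(axis=1)
    excluded = sorted(stats.index[n_failed >= min_failures])
    return SampleQCReport(
        rules=list(rules),
        failures=failures,
        n_failed=n_failed,
        excluded=excluded,
        min_failures=min_failures,
    )
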