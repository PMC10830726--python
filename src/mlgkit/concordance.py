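"""Cross-marker concordance, regional redundancy and descriptor review.

Three reporting views over MLG partitions:

* :func:`compare_partitions` — classify each accession as single
  (its own MLG) or multi (inside a redundancy group) under two
  partitions (e.g. SNP vs silico markers), count the Venn cells, and
  total up discrepancies (class mismatches plus both-multi accessions
  whose MLG sizes differ between the partitions).
* :func:`region_summary` — per region of origin, MLG-size categories
  C1 / C2 / C3-C5 / C6+ with percent distinct (C1 / total) and percent
  redundant, half-up rounded to one decimal from the same unrounded
  ratio.
* :func:`descriptor_concordance` — within selected multi-accession MLGs,
  count distinct descriptor classes per passport/characterization
  variable; a variable "scores one" for a case when exactly one class is
  present among accessions with data.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import defaultdict
from typing import Mapping, Sequence

import pandas as pd

from .io import DESCRIPTOR_VARIABLES, ND, SampleMeta
from .mlg import MLGPartition, round_half_up

__all__ = [
    "ConcordanceSummary",
    "compare_partitions",
    "region_summary",
    "region_percentages",
    "DescriptorConcordance",
    "descriptor_concordance",
]

SIZE_CATEGORIES = ("C1", "C2", "C3-C5", "C6+")


def _size_category(size: int) -> str:
    if size == 1:
        return "C1"
    if size == 2:
        return "C2"
    if size <= 5:
        return "C3-C5"
    return "C6+"


@dataclasses.dataclass
class ConcordanceSummary:
    n_common: int
    both_single: list[str]
    both_multi: list[str]
    single_a_multi_b: list[str]
    multi_a_single_b: list[str]
    differing_size_both_multi: list[str]

    @property
    def n_mismatch(self) -> int:
        return len(self.single_a_multi_b) + len(self.multi_a_single_b)

    @property
    def total_discrepancy(self) -> int:
        return self.n_mismatch + len(self.differing_size_both_multi)

    def to_dict(self) -> dict:
        return {
            "n_common": self.n_common,
            "n_both_single": len(self.both_single),
            "n_both_multi": len(self.both_multi),
            "n_single_a_multi_b": len(self.single_a_multi_b),
            "n_multi_a_single_b": len(self.multi_a_single_b),
            "n_differing_size_both_multi": len(self.differing_size_both_multi),
            "total_discrepancy": self.total_discrepancy,
            "venn": {
                "both_single": self.both_single,
                "both_multi": self.both_multi,
                "single_a_multi_b": self.single_a_multi_b,
                "multi_a_single_b": self.multi_a_single_b,
            },
        }


def compare_partitions(pa: MLGPartition, pb: MLGPartition) -> ConcordanceSummary:
    """Venn comparison of two partitions over their common units."""
    common = sorted(set(pa.assignment) & set(pb.assignment))
    if not common:
        raise ValueError("partitions share no samples")
    size_a = _unit_sizes(pa)
    size_b = _unit_sizes(pb)
    cells: dict[str, list[str]] = {k: [] for k in ("ss", "mm", "sm", "ms")}
    differ = []
    for u in common:
        a_single = size_a[u] == 1
        b_single = size_b[u] == 1
        key = ("s" if a_single else "m") + ("s" if b_single else "m")
        cells[key].append(u)
        if not a_single and not b_single and size_a[u] != size_b[u]:
            differ.append(u)
    return ConcordanceSummary(
        n_common=len(common),
        both_single=cells["ss"],
        both_multi=cells["mm"],
        single_a_multi_b=cells["sm"],
        multi_a_single_b=cells["ms"],
        differing_size_both_multi=differ,
    )


def _unit_sizes(p: MLGPartition) -> dict[str, int]:
    sizes: dict[str, int] = defaultdict(int)
    for _, g in p.assignment.items():
        sizes[g] += 1
    return {u: sizes[g] for u, g in p.assignment.items()}


# ---------------------------------------------------------------------------
# regional summaries


def region_percentages(
    c1: int, c2: int, c3_5: int, c6_plus: int, total: int | None = None
) -> tuple[float, float]:
    """(percent distinct, percent redundant) from size-category counts.

    The denominator is the category sum unless an external ``total`` is
    supplied; a disagreement between the two triggers a warning, not an
    error (published totals sometimes disagree with their category sums).
    """
    cat_sum = c1 + c2 + c3_5 + c6_plus
    denom = cat_sum if total is None else total
    if total is not None and total != cat_sum:
        warnings.warn(
            f"externally supplied total {total} differs from category sum {cat_sum}"
        )
    if denom <= 0:
        raise ValueError("region has no accessions")
    distinct = round_half_up(100.0 * c1 / denom, 1)
    redundant = round_half_up(100.0 * (denom - c1) / denom, 1)
    return distinct, redundant


def region_summary(
    p: MLGPartition,
    metas: Sequence[SampleMeta],
    totals: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-region MLG-size-category counts and redundancy percentages.

    Units with no known region are grouped under ``"unknown"``.
    """
    region_of = {m.sample_id: (m.region or "unknown") for m in metas}
    sizes = _unit_sizes(p)
    counts: dict[str, dict[str, int]] = defaultdict(lambda: dict.fromkeys(SIZE_CATEGORIES, 0))
    for u, size in sizes.items():
        counts[region_of.get(u, "unknown")][_size_category(size)] += 1
    rows = []
    for region in sorted(counts):
        c = counts[region]
        total = None if totals is None else totals.get(region)
        distinct, redundant = region_percentages(
            c["C1"], c["C2"], c["C3-C5"], c["C6+"], total
        )
        rows.append(
            {
                "region": region,
                **c,
                "total": sum(c.values()) if total is None else total,
                "pct_distinct": distinct,
                "pct_redundant": redundant,
            }
        )
    return pd.DataFrame(rows).set_index("region")


# ---------------------------------------------------------------------------
# descriptor concordance


@dataclasses.dataclass
class DescriptorConcordance:
    """Distinct-class counts per selected MLG case and descriptor variable.

    ``table`` holds one row per (case, variable): the number of distinct
    non-ND classes, and how many accessions had data out of the case
    total.  ``case_ones[case]`` counts variables with exactly one class;
    ``variable_ones[variable]`` counts cases with exactly one class, by
    default excluding cases where only a single accession had data for
    that variable (one record cannot show agreement).
    """

    table: pd.DataFrame
    case_ones: dict[str, int]
    variable_ones: dict[str, int]
    exclude_single_for_cases: bool
    exclude_single_for_variables: bool

    def to_dict(self) -> dict:
        return {
            "cases": self.case_ones,
            "variables": self.variable_ones,
            "rules": {
                "exclude_single_record_for_cases": self.exclude_single_for_cases,
                "exclude_single_record_for_variables": self.exclude_single_for_variables,
            },
            "table": self.table.reset_index().to_dict(orient="records"),
        }


def _classes(values: list[str], variable: str) -> set[str]:
    if variable == "common_names":
        names: set[str] = set()
        for v in values:
            names.update(x.strip() for x in v.split(";") if x.strip())
        return names
    return set(values)


def descriptor_concordance(
    p: MLGPartition,
    descriptors: pd.DataFrame,
    cases: Sequence[str],
    variables: Sequence[str] = tuple(DESCRIPTOR_VARIABLES),
    exclude_single_for_cases: bool = False,
    exclude_single_for_variables: bool = True,
) -> DescriptorConcordance:
    """Score descriptor agreement within the selected MLG cases.

    ``cases`` are MLG ids of ``p``.  Accessions without a descriptor row
    count toward the case total but contribute no data (as if ND).
    """
    groups = p.groups()
    rows = []
    case_ones: dict[str, int] = {}
    variable_ones: dict[str, int] = dict.fromkeys(variables, 0)
    for case in cases:
        if case not in groups:
            raise KeyError(f"case {case!r} is not an MLG id of the partition")
        members = groups[case]
        ones = 0
        for var in variables:
            vals = []
            for acc in members:
                if acc in descriptors.index:
                    v = str(descriptors.loc[acc, var])
                    if v != ND:
                        vals.append(v)
            classes = _classes(vals, var)
            n_classes = len(classes)
            rows.append(
                {
                    "case": case,
                    "variable": var,
                    "n_classes": n_classes,
                    "n_with_data": len(vals),
                    "n_total": len(members),
                }
            )
            is_one = n_classes == 1
            if is_one and not (exclude_single_for_cases and len(vals) < 2):
                ones += 1
            if is_one and not (exclude_single_for_variables and len(vals) < 2):
                variable_ones[var] += 1
        case_ones[case] = ones
    table = pd.DataFrame(rows).set_index(["case", "variable"])
    return DescriptorConcordance(
        table=table,
        case_ones=case_ones,
        variable_ones=variable_ones,
        exclude_single_for_cases=exclude_single_for_cases,
        exclude_single_for_variables=exclude_single_for_variables,
    )
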