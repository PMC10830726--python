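"""Cross-marker concordance, region summaries and descriptor review."""

import numpy as np
import pandas as pd
import pytest

from mlgkit.concordance import (
    compare_partitions,
    descriptor_concordance,
    region_percentages,
    region_summary,
)
from mlgkit.io import DESCRIPTOR_VARIABLES, ND, SampleMeta
from mlgkit.mlg import MLGPartition
from mlgkit.simulate import SimConfig, simulate_collection


def part(groups, metric="ibs"):
    assignment = {}
    for ms in groups:
        gid = min(ms)
        for s in ms:
            assignment[s] = gid
    return MLGPartition(assignment, threshold=0.015, linkage="nearest", metric=metric)


class TestComparePartitions:
    def test_identical_partitions_no_discrepancy(self):
        a = part([{"a", "b"}, {"c"}])
        assert compare_partitions(a, a).total_discrepancy == 0

    def test_multi_vs_singletons(self):
        a = part([{"a", "b"}, {"c"}])
        b = part([{"a"}, {"b"}, {"c"}])
        s = compare_partitions(a, b)
        assert s.both_single == ["c"]
        assert sorted(s.multi_a_single_b) == ["a", "b"]
        assert s.total_discrepancy == 2

    def test_differing_sizes_among_both_multi(self):
        a = part([{"a", "b"}, {"c", "d"}])
        b = part([{"a", "b"}, {"c", "d", "e"}])
        s = compare_partitions(a, b)
        assert sorted(s.differing_size_both_multi) == ["c", "d"]
        assert s.total_discrepancy == 2

    def test_symmetric_up_to_swapping_directions(self):
        a = part([{"a", "b"}, {"c"}, {"d"}])
        b = part([{"a"}, {"b"}, {"c", "d"}])
        s_ab = compare_partitions(a, b)
        s_ba = compare_partitions(b, a)
        assert sorted(s_ab.single_a_multi_b) == sorted(s_ba.multi_a_single_b)
        assert s_ab.total_discrepancy == s_ba.total_discrepancy

    def test_disjoint_sample_sets_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            compare_partitions(part([{"a"}]), part([{"z"}]))


class TestRegionSummary:
    def test_published_eastern_south_america_distinctness(self):
        distinct, redundant = region_percentages(399, 287, 413, 412)
        assert distinct == 26.4
        assert distinct + redundant == pytest.approx(100.0)

    def test_published_central_north_america_redundancy(self):
        distinct, redundant = region_percentages(74, 67, 108, 202)
        assert redundant == 83.6

    def test_published_africa_distinctness(self):
        distinct, _ = region_percentages(13, 6, 0, 0)
        assert distinct == 68.4

    def test_all_singleton_region(self):
        distinct, redundant = region_percentages(10, 0, 0, 0)
        assert distinct == 100.0 and redundant == 0.0

    def test_external_total_override_warns_on_disagreement(self):
        with pytest.warns(UserWarning, match="differs from category sum"):
            distinct, _ = region_percentages(10, 5, 0, 0, total=20)
        assert distinct == 50.0

    def test_region_table_from_partition(self):
        groups = [{"a1", "a2"}, {"a3"}, {"b1"}, {"b2", "b3", "b4"}]
        p = part(groups)
        metas = [SampleMeta(s, s.upper(), region="west" if s.startswith("a") else "east")
                 for g in groups for s in g]
        table = region_summary(p, metas)
        assert table.loc["west", "C1"] == 1 and table.loc["west", "C2"] == 2
        assert table.loc["east", "C3-C5"] == 3 and table.loc["east", "C1"] == 1
        assert table.loc["east", "pct_distinct"] == 25.0
        for _, row in table.iterrows():
            assert row["pct_distinct"] + row["pct_redundant"] == pytest.approx(100.0)

    def test_unknown_region_grouped(self):
        p = part([{"x"}])
        table = region_summary(p, [SampleMeta("x", "X", region="")])
        assert "unknown" in table.index


def case9_fixture():
    """Two accessions agreeing on 7 of the 9 reviewed variables (the
    published worked example: disagreement only on collection date and
    central-leaf shape, all variables with 2/2 data)."""
    rows = []
    for acc, date, shape in [("GUA80", "1978", "lanceolate"),
                             ("GUA89", "1982", "ovoid")]:
        rows.append({
            "accession_id": acc,
            "biological_status": "landrace",
            "country": "GTM",
            "common_names": "izote",
            "collection_date": date,
            "shape_central_leaf": shape,
            "petiole_color": "red",
            "color_first_expanded_leaf": "purple",
            "number_leaf_lobes": "5",
            "color_root_pulp": "white",
        })
    return pd.DataFrame(rows).set_index("accession_id")


class TestDescriptorConcordance:
    def test_identical_root_pulp_scores_one_with_full_data(self):
        desc = case9_fixture()
        p = part([{"GUA80", "GUA89"}])
        dc = descriptor_concordance(p, desc, ["GUA80"])
        row = dc.table.loc[("GUA80", "color_root_pulp")]
        assert row["n_classes"] == 1
        assert row["n_with_data"] == 2 and row["n_total"] == 2

    def test_case_counts_of_ones_is_seven(self):
        desc = case9_fixture()
        p = part([{"GUA80", "GUA89"}])
        dc = descriptor_concordance(p, desc, ["GUA80"])
        assert dc.case_ones["GUA80"] == 7

    def test_single_record_excluded_from_variable_counts(self):
        desc = case9_fixture()
        desc.loc["GUA89", "petiole_color"] = ND  # only one accession with data
        p = part([{"GUA80", "GUA89"}])
        dc = descriptor_concordance(p, desc, ["GUA80"])
        assert dc.variable_ones["petiole_color"] == 0
        # but the per-case count keeps it by default (rule configurable)
        assert dc.case_ones["GUA80"] == 7
        strict = descriptor_concordance(p, desc, ["GUA80"],
                                        exclude_single_for_cases=True)
        assert strict.case_ones["GUA80"] == 6

    def test_common_names_counted_as_distinct_names(self):
        desc = case9_fixture()
        desc.loc["GUA89", "common_names"] = "izote;cassada"
        p = part([{"GUA80", "GUA89"}])
        dc = descriptor_concordance(p, desc, ["GUA80"])
        assert dc.table.loc[("GUA80", "common_names"), "n_classes"] == 2

    def test_absent_case_rejected(self):
        p = part([{"GUA80", "GUA89"}])
        with pytest.raises(KeyError, match="nope"):
            descriptor_concordance(p, case9_fixture(), ["nope"])

    def test_error_free_synthetic_mlgs_score_one_everywhere(self):
        cfg = SimConfig(seed=3, n_genotypes=10, clones_per_genotype=3,
                        n_snp_markers=30, n_silico_markers=30,
                        n_dna_rep_pairs=0, n_extract_rep_pairs=0,
                        n_ind_rep_trios=0, n_lowq_samples=0,
                        descriptor_error_rate=0.0, descriptor_nd_rate=0.2)
        r = simulate_collection(cfg)
        truth_groups = r.truth.redundancy_partition()
        p = part([set(accs) for accs in truth_groups.values()])
        cases = [min(accs) for accs in truth_groups.values() if len(accs) > 1]
        dc = descriptor_concordance(p, r.descriptors, cases)
        populated = dc.table[dc.table["n_with_data"] > 0]
        assert (populated["n_classes"] == 1).all()
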