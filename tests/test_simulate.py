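"""Synthetic-collection generator: no-noise limits, closed-form oracles,
reproducibility and the replicate-error structure."""

import itertools

import numpy as np
import pytest

from mlgkit.calibration import enumerate_replicate_pairs
from mlgkit.distances import ibs_distance, jaccard_distance
from mlgkit.simulate import SimConfig, SimTruth, simulate_collection, truth_partition


def replicate_pair_distances(result, dm, cls=None):
    pairs = enumerate_replicate_pairs(result.samples)
    return np.array(
        [dm.loc(p.sample_a, p.sample_b) for p in pairs
         if cls is None or p.replicate_class == cls]
    )


class TestNoNoiseLimit:
    def test_replicate_pairs_at_distance_zero(self, sim_clean):
        for dist_fn, matrix in [(ibs_distance, sim_clean.snp),
                                (jaccard_distance, sim_clean.silico)]:
            dm = dist_fn(matrix)
            ds = replicate_pair_distances(sim_clean, dm)
            assert len(ds) > 0
            assert np.all(ds == 0.0)

    def test_clones_identical_to_founder_copies(self, sim_clean):
        parts = truth_partition(sim_clean.truth)
        dm = ibs_distance(sim_clean.snp)
        for samples in parts.values():
            for a, b in itertools.combinations(samples, 2):
                assert dm.loc(a, b) == 0.0


class TestClosedFormFounderDistance:
    """Expected IBS distance between independent founders at fixed allele
    frequency, from exhaustive enumeration of the 3x3 genotype-pair table."""

    @staticmethod
    def hw_expected_distance(p):
        probs = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}
        e = 0.0
        var_term = 0.0
        for ga, pa in probs.items():
            for gb, pb in probs.items():
                d = abs(ga - gb) / 2.0  # per-locus distance contribution
                e += pa * pb * d
                var_term += pa * pb * d * d
        return e, var_term - e * e

    def test_monte_carlo_mean_within_three_se(self):
        p = 0.3
        cfg = SimConfig(
            seed=123,
            n_genotypes=2,
            clones_per_genotype=1,
            n_snp_markers=5000,
            n_silico_markers=10,
            allele_freq_law=(p, p),
            founder_inbreeding=0.0,
            err_dna=0.0,
            err_extract=0.0,
            err_ind=0.0,
            missing_rate=0.0,
            bad_marker_fraction=0.0,
            n_dna_rep_pairs=0,
            n_extract_rep_pairs=0,
            n_ind_rep_trios=0,
            n_lowq_samples=0,
        )
        r = simulate_collection(cfg)
        dm = ibs_distance(r.snp)
        observed = dm.values[0, 1]
        expected, var = self.hw_expected_distance(p)
        se = np.sqrt(var / cfg.n_snp_markers)
        assert abs(observed - expected) < 3 * se


class TestDnaReplicateErrorOracle:
    """Mean DNA-replicate distance matches exhaustive enumeration of the
    per-allele miscall model (flip each copy with probability eps)."""

    @staticmethod
    def expected_pair_distance(p, eps):
        hw = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}

        def dosage_dist(g):
            # g' = g + Binom(2-g, eps) - Binom(g, eps)
            out = {}
            for up in range(2 - g + 1):
                pu = _binom_pmf(2 - g, up, eps)
                for down in range(g + 1):
                    pd = _binom_pmf(g, down, eps)
                    out[g + up - down] = out.get(g + up - down, 0.0) + pu * pd
            return out

        e = 0.0
        var_term = 0.0
        for g, pg in hw.items():
            da = dosage_dist(g)
            for ga, pa in da.items():
                for gb, pb in da.items():
                    d = abs(ga - gb) / 2.0
                    e += pg * pa * pb * d
                    var_term += pg * pa * pb * d * d
        return e, var_term - e * e

    def test_mean_dna_pair_distance(self):
        p, eps = 0.3, 0.002
        cfg = SimConfig(
            seed=42,
            n_genotypes=12,
            clones_per_genotype=1,
            n_snp_markers=5000,
            n_silico_markers=10,
            allele_freq_law=(p, p),
            founder_inbreeding=0.0,
            err_dna=eps,
            err_extract=eps,
            err_ind=eps,
            missing_rate=0.0,
            bad_marker_fraction=0.0,
            depth_law=(np.log(12.0), 0.0),  # depth = 12 -> error multiplier 1
            n_dna_rep_pairs=10,
            n_extract_rep_pairs=0,
            n_ind_rep_trios=0,
            n_lowq_samples=0,
        )
        r = simulate_collection(cfg)
        dm = ibs_distance(r.snp)
        ds = replicate_pair_distances(r, dm, cls="dna")
        expected, var = self.expected_pair_distance(p, eps)
        se = np.sqrt(var / (cfg.n_snp_markers * len(ds)))
        assert len(ds) == 10
        assert abs(ds.mean() - expected) < 3 * se


def _binom_pmf(n, k, p):
    from math import comb

    return comb(n, k) * p**k * (1 - p) ** (n - k)


class TestReproducibilityAndStructure:
    def test_same_seed_identical_outputs(self):
        a = simulate_collection(SimConfig(seed=5, n_genotypes=8, n_snp_markers=100,
                                          n_silico_markers=100, n_dna_rep_pairs=2,
                                          n_extract_rep_pairs=2, n_ind_rep_trios=2))
        b = simulate_collection(SimConfig(seed=5, n_genotypes=8, n_snp_markers=100,
                                          n_silico_markers=100, n_dna_rep_pairs=2,
                                          n_extract_rep_pairs=2, n_ind_rep_trios=2))
        assert np.array_equal(a.snp.values, b.snp.values, equal_nan=True)
        assert np.array_equal(a.silico.values, b.silico.values, equal_nan=True)
        assert a.samples == b.samples
        assert a.snp_meta.equals(b.snp_meta)
        assert a.descriptors.equals(b.descriptors)
        assert a.truth.to_dict() == b.truth.to_dict()

    def test_increasing_ind_error_increases_ind_distance(self):
        def mean_ind(err, seeds=(0, 1, 2)):
            out = []
            for s in seeds:
                cfg = SimConfig(seed=s, n_genotypes=10, n_snp_markers=800,
                                n_silico_markers=10, err_dna=0.0005, err_extract=0.001,
                                err_ind=err, n_dna_rep_pairs=2, n_extract_rep_pairs=2,
                                n_ind_rep_trios=4, n_lowq_samples=0)
                r = simulate_collection(cfg)
                dm = ibs_distance(r.snp)
                out.append(replicate_pair_distances(r, dm, cls="ind").mean())
            return np.mean(out)

        assert mean_ind(0.001) < mean_ind(0.004) < mean_ind(0.012)

    def test_class_means_order_dna_extract_ind(self):
        pooled = {c: [] for c in ("dna", "extract", "ind")}
        for seed in range(5):
            r = simulate_collection(SimConfig(seed=seed, n_snp_markers=1000,
                                              n_silico_markers=10))
            dm = ibs_distance(r.snp)
            for c in pooled:
                pooled[c].extend(replicate_pair_distances(r, dm, cls=c))
        means = {c: np.mean(v) for c, v in pooled.items()}
        assert means["dna"] < means["extract"] < means["ind"]

    def test_replicate_groups_share_accession(self, sim_default):
        by_group = {}
        for m in sim_default.samples:
            if m.replicate_group:
                by_group.setdefault(m.replicate_group, set()).add(m.accession_id)
        assert by_group and all(len(a) == 1 for a in by_group.values())

    def test_lowq_metadata_consistent_with_modes(self, sim_default):
        modes = dict(sim_default.truth.lowq_samples)
        meta = {m.sample_id: m for m in sim_default.samples}
        for sid, mode in modes.items():
            if mode == "low_depth":
                assert meta[sid].tagcount_total < 1_500_000
                assert meta[sid].tagcount_unique < 230_000
            if mode == "predigested":
                assert meta[sid].target_qc == "downshifted"

    def test_unordered_error_rates_warn(self):
        with pytest.warns(UserWarning, match="not ordered"):
            SimConfig(err_dna=0.01, err_extract=0.001, err_ind=0.001)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_genotypes"):
            SimConfig(n_genotypes=0)
        with pytest.raises(ValueError, match="probability"):
            SimConfig(missing_rate=1.5)


class TestTruthPartition:
    def test_three_genotypes_two_clones(self):
        cfg = SimConfig(seed=1, n_genotypes=3, clones_per_genotype=2,
                        n_snp_markers=20, n_silico_markers=20, n_dna_rep_pairs=0,
                        n_extract_rep_pairs=0, n_ind_rep_trios=0, n_lowq_samples=0)
        r = simulate_collection(cfg)
        parts = truth_partition(r.truth)
        assert len(parts) == 3
        assert all(len(v) == 2 for v in parts.values())

    def test_contaminated_sample_keeps_nominal_founder_and_is_flagged(self):
        cfg = SimConfig(seed=2, n_genotypes=6, n_snp_markers=50, n_silico_markers=50,
                        n_dna_rep_pairs=0, n_extract_rep_pairs=0, n_ind_rep_trios=0,
                        n_lowq_samples=2)
        r = simulate_collection(cfg)
        contaminated = [s for s, m in r.truth.lowq_samples if m == "contaminated"]
        assert contaminated
        parts = truth_partition(r.truth)
        for sid in contaminated:
            assert any(sid in ss for ss in parts.values())

    def test_empty_truth_gives_empty_partition(self):
        t = SimTruth(sample_to_founder={}, accession_to_founder={}, lowq_samples=[])
        assert truth_partition(t) == {}


class TestWriteCollection:
    def test_emits_all_csvs_and_truth(self, tmp_path, sim_clean):
        import json

        from mlgkit.io import (
            read_descriptors,
            read_marker_matrix,
            read_marker_meta,
            read_sample_meta,
        )
        from mlgkit.simulate import write_collection

        write_collection(sim_clean, tmp_path)
        snp = read_marker_matrix(tmp_path / "snp_matrix.csv", "snp")
        assert np.array_equal(snp.values, sim_clean.snp.values, equal_nan=True)
        silico = read_marker_matrix(tmp_path / "silico_matrix.csv", "silico")
        assert silico.n_markers == sim_clean.silico.n_markers
        meta = read_marker_meta(tmp_path / "snp_meta.csv", "snp")
        assert list(meta.index) == sim_clean.snp.marker_ids
        samples = read_sample_meta(tmp_path / "sample_meta.csv")
        assert samples == sim_clean.samples
        desc = read_descriptors(tmp_path / "descriptors.csv")
        assert desc.equals(sim_clean.descriptors)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["sample_to_founder"] == sim_clean.truth.sample_to_founder
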