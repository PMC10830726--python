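import numpy as np
import pytest

from mlgkit.io import DistanceMatrix, MarkerMatrix
from mlgkit.simulate import SimConfig, simulate_collection


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition synthetic collection shared across tests."""
    return simulate_collection(SimConfig(seed=7))


@pytest.fixture(scope="session")
def sim_clean():
    """Noise-free collection: replicates must be byte-identical genotypes."""
    cfg = SimConfig(
        seed=11,
        n_genotypes=12,
        n_snp_markers=300,
        n_silico_markers=300,
        err_dna=0.0,
        err_extract=0.0,
        err_ind=0.0,
        missing_rate=0.0,
        bad_marker_fraction=0.0,
        n_lowq_samples=0,
        n_dna_rep_pairs=3,
        n_extract_rep_pairs=3,
        n_ind_rep_trios=2,
    )
    return simulate_collection(cfg)


def make_dm(labels, entries, metric="ibs"):
    """DistanceMatrix from {(a, b): d} pairs (zero elsewhere off-diagonal)."""
    n = len(labels)
    pos = {s: i for i, s in enumerate(labels)}
    m = np.zeros((n, n))
    for (a, b), d in entries.items():
        m[pos[a], pos[b]] = m[pos[b], pos[a]] = d
    return DistanceMatrix(list(labels), m, metric)


def snp_matrix(rows, sample_ids=None, marker_ids=None):
    """MarkerMatrix from a list of per-marker dosage lists (None = missing)."""
    vals = np.array(
        [[np.nan if v is None else float(v) for v in r] for r in rows], dtype=float
    )
    mids = marker_ids or [f"m{i}" for i in range(len(rows))]
    sids = sample_ids or [f"s{j}" for j in range(vals.shape[1])]
    return MarkerMatrix(mids, sids, vals, "snp")


def silico_matrix(rows, sample_ids=None, marker_ids=None):
    vals = np.array(
        [[np.nan if v is None else float(v) for v in r] for r in rows], dtype=float
    )
    mids = marker_ids or [f"m{i}" for i in range(len(rows))]
    sids = sample_ids or [f"s{j}" for j in range(vals.shape[1])]
    return MarkerMatrix(mids, sids, vals, "silico")
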