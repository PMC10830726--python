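"""Pairwise genetic distances from filtered genotype matrices.

Two metrics, matching the two marker chemistries:

* **IBS distance** (codominant SNP dosages): one minus the proportion of
  shared alleles over loci called in both samples.  At a locus with
  dosages ``ga, gb`` the shared-allele count is ``2 - |ga - gb|``, so the
  distance is ``1 - sum(2 - |ga - gb|) / (2 * n_called_loci)``.
* **Jaccard distance** (dominant presence/absence markers): with ``a``
  joint presences, ``b``/``c`` one-sided presences over co-called loci,
  ``(b + c) / (a + b + c)``.  Joint absences carry no information for a
  dominant marker and are excluded.

Missing data are handled pairwise-complete: each pair uses exactly the
loci called in both samples.  Degenerate pairs (no usable loci) receive a
flagged sentinel — 1.0 for IBS, 0.0 for Jaccard — instead of raising, so
one bad sample cannot abort a full run; the flags travel with the
:class:`~mlgkit.io.DistanceMatrix`.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import DistanceMatrix, MarkerMatrix

__all__ = ["ibs_distance", "jaccard_distance"]


def _indicator_planes(m: MarkerMatrix, codes) -> tuple[list[np.ndarray], np.ndarray]:
    called = ~np.isnan(m.values)
    planes = [((m.values == k) & called).astype(float) for k in codes]
    return planes, called.astype(float)


def ibs_distance(m: MarkerMatrix) -> DistanceMatrix:
    """IBS distance matrix for an SNP dosage matrix.

    Vectorized via dosage-indicator cross-products: with ``I_k`` the
    (markers x samples) indicator of dosage ``k``, the total allele
    mismatch between samples is ``sum_{j,k} |j - k| * I_j^T I_k``.
    """
    if m.marker_type != "snp":
        raise ValueError(f"ibs_distance requires marker_type 'snp', got {m.marker_type!r}")
    if m.n_samples < 2:
        raise ValueError("ibs_distance needs at least 2 samples")
    (i0, i1, i2), called = _indicator_planes(m, (0, 1, 2))
    mismatch = (
        i0.T @ i1 + i1.T @ i0 + i1.T @ i2 + i2.T @ i1 + 2.0 * (i0.T @ i2 + i2.T @ i0)
    )
    valid = called.T @ called
    degenerate = valid == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(degenerate, 1.0, mismatch / np.maximum(2.0 * valid, 1e-300))
    return _finish(m, dist, degenerate, "ibs")


def jaccard_distance(m: MarkerMatrix) -> DistanceMatrix:
    """Jaccard distance matrix for a dominant presence/absence matrix."""
    if m.marker_type != "silico":
        raise ValueError(
            f"jaccard_distance requires marker_type 'silico', got {m.marker_type!r}"
        )
    if m.n_samples < 2:
        raise ValueError("jaccard_distance needs at least 2 samples")
    (i0, i1), _ = _indicator_planes(m, (0, 1))
    a = i1.T @ i1
    bc = i1.T @ i0 + i0.T @ i1
    denom = a + bc
    degenerate = denom == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(degenerate, 0.0, bc / np.maximum(denom, 1e-300))
    return _finish(m, dist, degenerate, "jaccard")


def _finish(
    m: MarkerMatrix, dist: np.ndarray, degenerate: np.ndarray, metric: str
) -> DistanceMatrix:
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)  # symmetrize float jitter
    iu, ju = np.nonzero(np.triu(degenerate, k=1))
    pairs = [(m.sample_ids[i], m.sample_ids[j]) for i, j in zip(iu, ju)]
    if pairs:
        warnings.warn(
            f"{len(pairs)} sample pair(s) had no informative loci; "
            f"distance set to sentinel and flagged",
            stacklevel=3,
        )
    return DistanceMatrix(m.sample_ids, dist, metric, pairs)
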