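"""Synthetic clonal collections with a replicate hierarchy and ground truth.

The generator emulates the data a genebank genotyping campaign produces
for a clonally propagated crop:

* **founder genotypes** — distinct multilocus genotypes; SNP dosages are
  drawn per marker from a founder allele-frequency law, with an
  inbreeding coefficient F pushing individuals below Hardy-Weinberg
  heterozygosity (clonal landraces carry correlated allele copies).
  Dominant (presence/absence) states are Bernoulli draws from a
  per-marker presence frequency.
* **accessions** — each founder is copied into 1+ accessions (the true
  redundancy the analysis must recover).
* **replicate hierarchy** — a subset of accessions carries DNA-level
  pairs (same DNA assayed twice), extraction-level pairs and
  individual-level trios, with per-allele miscall rates ordered
  err_dna <= err_extract <= err_ind.  Ordinary samples behave like
  independent individuals (err_ind).
* **per-marker error heterogeneity** — markers with low simulated
  sequencing depth carry up to twice the nominal miscall rate, so the
  depth/reproducibility filter cascade measurably cleans replicate
  distances.
* **failure modes** — injected low-quality samples: ``low_depth`` (tag
  counts below the QC thresholds, extra missingness), ``contaminated``
  (cells mix alleles of two founders, inflating heterozygosity) and
  ``predigested`` (downshifted library, depressed call rate).

A miscall flips one allele copy: SNP dosage moves by +-1 within bounds
(a heterozygote read as homozygote and vice versa); a dominant score is
a bit-flip.  Every output is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    DESCRIPTOR_VARIABLES,
    ND,
    MarkerMatrix,
    SampleMeta,
    write_descriptors,
    write_marker_matrix,
    write_marker_meta,
    write_sample_meta,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "simulate_collection",
    "truth_partition",
    "write_collection",
]

LOWQ_MODES = ("low_depth", "contaminated", "predigested")

# country -> region, loosely mirroring a Latin-American-centred collection
_ORIGINS = [
    ("COL", "Western South America", 0.35),
    ("PER", "Western South America", 0.08),
    ("VEN", "Western South America", 0.05),
    ("BRA", "Eastern South America", 0.22),
    ("PRY", "Eastern South America", 0.05),
    ("CUB", "Central/North America & Caribbean", 0.06),
    ("GTM", "Central/North America & Caribbean", 0.04),
    ("MEX", "Central/North America & Caribbean", 0.04),
    ("IDN", "Asia", 0.05),
    ("THA", "Asia", 0.03),
    ("NGA", "Africa", 0.03),
]

_DESCRIPTOR_VOCAB = {
    "shape_central_leaf": [
        "lanceolate",
        "ovoid",
        "oblong-lanceolate",
        "linear-pandurate",
        "straight",
    ],
    "petiole_color": ["green", "red", "purple", "yellowish-green", "green-red"],
    "color_first_expanded_leaf": ["light-green", "dark-green", "purple", "green-purple"],
    "number_leaf_lobes": ["3", "5", "7", "9"],
    "color_root_pulp": ["white", "cream", "yellow", "pink"],
}


@dataclasses.dataclass
class SimConfig:
    """Study conditions for one synthetic collection.

    Defaults give a seconds-scale grid: 40 founder genotypes with 2-4
    accessions each, 2,000 SNP + 2,000 dominant markers, replicate
    groups scaled down from the study design (10 DNA pairs, 9 extraction
    pairs, 7 individual trios), per-allele miscall rates matching the
    post-filter replicate distances the calibration relies on.
    """

    n_genotypes: int = 40
    clones_per_genotype: int | tuple[int, int] = (2, 4)
    n_snp_markers: int = 2000
    n_silico_markers: int = 2000
    allele_freq_law: tuple[float, float] = (0.01, 0.3)
    presence_freq_law: tuple[float, float] = (0.02, 0.5)
    founder_inbreeding: float = 0.5
    err_dna: float = 0.001
    err_extract: float = 0.002
    err_ind: float = 0.0025
    missing_rate: float = 0.02
    bad_marker_fraction: float = 0.05
    bad_marker_missing_rate: float = 0.25
    n_dna_rep_pairs: int = 10
    n_extract_rep_pairs: int = 9
    n_ind_rep_trios: int = 7
    n_lowq_samples: int = 3
    contamination_fraction: float = 0.5
    lowq_error_multiplier: float = 4.0
    lowq_extra_missing: float = 0.30
    depth_law: tuple[float, float] = (2.5, 0.5)
    mapped_fraction: float = 0.87
    descriptor_error_rate: float = 0.05
    descriptor_nd_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 1:
            raise ValueError("n_genotypes must be >= 1")
        for name in (
            "founder_inbreeding",
            "err_dna",
            "err_extract",
            "err_ind",
            "missing_rate",
            "bad_marker_fraction",
            "bad_marker_missing_rate",
            "contamination_fraction",
            "lowq_extra_missing",
            "mapped_fraction",
            "descriptor_error_rate",
            "descriptor_nd_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in (
            "n_snp_markers",
            "n_silico_markers",
            "n_dna_rep_pairs",
            "n_extract_rep_pairs",
            "n_ind_rep_trios",
            "n_lowq_samples",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.err_dna <= self.err_extract <= self.err_ind:
            warnings.warn(
                "replicate-class error rates are not ordered "
                "err_dna <= err_extract <= err_ind; class mean distances "
                "will not follow the expected ordering"
            )

    def clones_range(self) -> tuple[int, int]:
        c = self.clones_per_genotype
        if isinstance(c, int):
            if c < 1:
                raise ValueError("clones_per_genotype must be >= 1")
            return (c, c)
        lo, hi = c
        if lo < 1 or hi < lo:
            raise ValueError("clones_per_genotype range must satisfy 1 <= lo <= hi")
        return (int(lo), int(hi))


@dataclasses.dataclass
class SimTruth:
    """Ground truth: founder assignments, injected failures, redundancy."""

    sample_to_founder: dict[str, str]
    accession_to_founder: dict[str, str]
    lowq_samples: list[tuple[str, str]]  # (sample_id, failure mode)
    tracking_errors: list[str] = dataclasses.field(default_factory=list)

    def redundancy_partition(self) -> dict[str, list[str]]:
        """True partition of accessions by founder genotype."""
        out: dict[str, list[str]] = {}
        for acc, f in self.accession_to_founder.items():
            out.setdefault(f, []).append(acc)
        return {f: sorted(a) for f, a in sorted(out.items())}

    def to_dict(self) -> dict:
        return {
            "sample_to_founder": self.sample_to_founder,
            "accession_to_founder": self.accession_to_founder,
            "lowq_samples": [{"sample_id": s, "mode": m} for s, m in self.lowq_samples],
            "tracking_errors": self.tracking_errors,
            "redundancy_partition": self.redundancy_partition(),
        }


@dataclasses.dataclass
class SimResult:
    snp: MarkerMatrix
    silico: MarkerMatrix
    snp_meta: pd.DataFrame
    silico_meta: pd.DataFrame
    samples: list[SampleMeta]
    descriptors: pd.DataFrame
    truth: SimTruth


def truth_partition(truth: SimTruth) -> dict[str, list[str]]:
    """Partition of *samples* by true founder genotype."""
    out: dict[str, list[str]] = {}
    for s, f in truth.sample_to_founder.items():
        out.setdefault(f, []).append(s)
    return {f: sorted(ss) for f, ss in sorted(out.items())}


# ---------------------------------------------------------------------------


def _founder_snp(rng, n_markers, n_geno, p, inbreeding):
    """Dosages with inbreeding: identical copies with probability F."""
    P = np.broadcast_to(p[:, None], (n_markers, n_geno))
    ibd = rng.random((n_markers, n_geno)) < inbreeding
    one = (rng.random((n_markers, n_geno)) < P).astype(int)
    hw = rng.binomial(2, P)
    return np.where(ibd, 2 * one, hw)


def _miscall_snp(rng, g, eps):
    """Per-allele-copy flips: dosage +-1 within bounds."""
    up = rng.binomial(2 - g, eps)
    down = rng.binomial(g, eps)
    return g + up - down


def simulate_collection(cfg: SimConfig) -> SimResult:
    """Generate one collection plus ground truth, reproducibly from the seed."""
    rng = np.random.default_rng(cfg.seed)

    # founder genotypes -----------------------------------------------------
    lo_p, hi_p = cfg.allele_freq_law
    p = rng.uniform(lo_p, hi_p, cfg.n_snp_markers)
    G_snp = _founder_snp(rng, cfg.n_snp_markers, cfg.n_genotypes, p, cfg.founder_inbreeding)
    lo_q, hi_q = cfg.presence_freq_law
    q = rng.uniform(lo_q, hi_q, cfg.n_silico_markers)
    G_sil = (rng.random((cfg.n_silico_markers, cfg.n_genotypes)) < q[:, None]).astype(int)

    # accessions ------------------------------------------------------------
    clo, chi = cfg.clones_range()
    clones = (
        np.full(cfg.n_genotypes, clo)
        if clo == chi
        else rng.integers(clo, chi + 1, cfg.n_genotypes)
    )
    founder_ids = [f"G{k:03d}" for k in range(cfg.n_genotypes)]
    accessions: list[tuple[str, str]] = []  # (accession_id, founder_id)
    acc_n = 0
    for k, f in enumerate(founder_ids):
        for _ in range(int(clones[k])):
            acc_n += 1
            accessions.append((f"ACC{acc_n:04d}", f))

    # origins and passport status per founder, copied to its accessions ----
    origin_p = np.array([w for _, _, w in _ORIGINS])
    origin_p = origin_p / origin_p.sum()
    origin_idx = rng.choice(len(_ORIGINS), cfg.n_genotypes, p=origin_p)
    status = rng.choice(
        ["landrace", "breeding_line", "unknown"], cfg.n_genotypes, p=[0.85, 0.12, 0.03]
    )

    # replicate hierarchy ---------------------------------------------------
    # one replicate group per replicated accession, spread across distinct
    # founder genotypes (the study's replicated accessions were distinct
    # accessions drawn from across the collection, not clones of one another)
    plan = (
        [("dna", 2)] * cfg.n_dna_rep_pairs
        + [("extract", 2)] * cfg.n_extract_rep_pairs
        + [("ind", 3)] * cfg.n_ind_rep_trios
    )
    if len(plan) > cfg.n_genotypes:
        raise ValueError(
            f"{len(plan)} replicate groups requested but only "
            f"{cfg.n_genotypes} founder genotypes available to host them"
        )
    first_acc_of_founder: dict[str, int] = {}
    for i, (_, f) in enumerate(accessions):
        first_acc_of_founder.setdefault(f, i)
    plan_by_index = {
        first_acc_of_founder[founder_ids[k]]: (k, plan[k]) for k in range(len(plan))
    }
    samples: list[SampleMeta] = []
    sample_founder: dict[str, str] = {}
    sample_class: dict[str, str] = {}
    for i, (acc, f) in enumerate(accessions):
        cid, region, _ = _ORIGINS[origin_idx[founder_ids.index(f)]]
        common = dict(
            accession_id=acc,
            region=region,
            country=cid,
            biological_status=str(status[founder_ids.index(f)]),
        )
        if i in plan_by_index:
            gnum, (cls, k) = plan_by_index[i]
            gid = f"RG{gnum:03d}"
            for r in range(k):
                sid = f"{acc}.{chr(ord('a') + r)}"
                samples.append(
                    SampleMeta(
                        sample_id=sid,
                        replicate_class=cls,
                        replicate_group=gid,
                        **common,
                    )
                )
                sample_founder[sid] = f
                sample_class[sid] = cls
        else:
            sid = f"{acc}.a"
            samples.append(SampleMeta(sample_id=sid, **common))
            sample_founder[sid] = f
            sample_class[sid] = "none"

    # low-quality injections (ordinary samples only) ------------------------
    ordinary = [s.sample_id for s in samples if s.replicate_class == "none"]
    n_lowq = min(cfg.n_lowq_samples, len(ordinary))
    lowq_ids = (
        sorted(rng.choice(ordinary, size=n_lowq, replace=False).tolist())
        if n_lowq
        else []
    )
    lowq_mode = {sid: LOWQ_MODES[i % len(LOWQ_MODES)] for i, sid in enumerate(lowq_ids)}

    # per-marker technical statistics and error multipliers ------------------
    mu_d, sd_d = cfg.depth_law
    snp_depth = rng.lognormal(mu_d, sd_d, cfg.n_snp_markers)
    sil_depth = rng.lognormal(mu_d, sd_d, cfg.n_silico_markers)
    # low-depth markers miscall more often; the depth-12 filter line marks
    # the scale at which error reaches its nominal class rate
    f_snp = np.clip(12.0 / snp_depth, 0.5, 2.0)
    f_sil = np.clip(12.0 / sil_depth, 0.5, 2.0)

    snp_meta = pd.DataFrame(
        {
            "avg_marker_count": snp_depth,
            "cv_marker_count": np.abs(rng.normal(0.4, 0.15, cfg.n_snp_markers)),
            "rep_avg": np.clip(
                1.0
                - 0.01 * f_snp
                - np.abs(rng.normal(0.0, 0.003, cfg.n_snp_markers)),
                0.8,
                1.0,
            ),
            "mapped": rng.random(cfg.n_snp_markers) < cfg.mapped_fraction,
        },
        index=pd.Index([f"snp{i:05d}" for i in range(cfg.n_snp_markers)], name="marker_id"),
    )
    silico_meta = pd.DataFrame(
        {
            "avg_read_depth": sil_depth,
            "cv_read_depth": np.abs(rng.normal(0.45, 0.15, cfg.n_silico_markers)),
            "reproducibility": np.clip(
                1.0
                - 0.01 * f_sil
                - np.abs(rng.normal(0.0, 0.003, cfg.n_silico_markers)),
                0.8,
                1.0,
            ),
            "mapped": rng.random(cfg.n_silico_markers) < cfg.mapped_fraction,
        },
        index=pd.Index(
            [f"sil{i:05d}" for i in range(cfg.n_silico_markers)], name="marker_id"
        ),
    )

    # per-marker missingness (a small fraction of markers is call-rate poor)
    snp_miss = np.full(cfg.n_snp_markers, cfg.missing_rate)
    snp_miss[rng.random(cfg.n_snp_markers) < cfg.bad_marker_fraction] = (
        cfg.bad_marker_missing_rate
    )
    sil_miss = np.full(cfg.n_silico_markers, cfg.missing_rate)
    sil_miss[rng.random(cfg.n_silico_markers) < cfg.bad_marker_fraction] = (
        cfg.bad_marker_missing_rate
    )

    class_err = {"dna": cfg.err_dna, "extract": cfg.err_extract, "ind": cfg.err_ind}
    founder_pos = {f: k for k, f in enumerate(founder_ids)}

    # observed genotypes -----------------------------------------------------
    X_snp = np.empty((cfg.n_snp_markers, len(samples)))
    X_sil = np.empty((cfg.n_silico_markers, len(samples)))
    tag_total = np.empty(len(samples))
    tag_unique = np.empty(len(samples))
    target_qc = ["good"] * len(samples)

    for j, s in enumerate(samples):
        sid = s.sample_id
        fidx = founder_pos[sample_founder[sid]]
        g = G_snp[:, fidx].copy()
        b = G_sil[:, fidx].copy()
        mode = lowq_mode.get(sid)
        err_mult, extra_miss = 1.0, 0.0
        if mode == "contaminated":
            if cfg.n_genotypes > 1:
                other = int((fidx + 1 + rng.integers(0, cfg.n_genotypes - 1)) % cfg.n_genotypes)
            else:
                other = fidx
            mix = rng.random(cfg.n_snp_markers) < cfg.contamination_fraction
            g2 = G_snp[:, other]
            # a contaminated cell reads one allele from each mixed genotype
            mixed = (rng.random(cfg.n_snp_markers) < g / 2.0).astype(int) + (
                rng.random(cfg.n_snp_markers) < g2 / 2.0
            ).astype(int)
            g = np.where(mix, mixed, g)
            mix_b = rng.random(cfg.n_silico_markers) < cfg.contamination_fraction
            b = np.where(mix_b, np.maximum(b, G_sil[:, other]), b)
        elif mode in ("low_depth", "predigested"):
            err_mult = cfg.lowq_error_multiplier
            extra_miss = cfg.lowq_extra_missing
            target_qc[j] = "downshifted"

        base = class_err[sample_class[sid]] if sample_class[sid] != "none" else cfg.err_ind
        eps_snp = np.minimum(base * f_snp * err_mult, 0.45)
        eps_sil = np.minimum(base * f_sil * err_mult, 0.45)
        g = _miscall_snp(rng, g, eps_snp)
        flip = rng.random(cfg.n_silico_markers) < eps_sil
        b = np.where(flip, 1 - b, b)

        miss_s = rng.random(cfg.n_snp_markers) < np.clip(snp_miss + extra_miss, 0, 1)
        miss_b = rng.random(cfg.n_silico_markers) < np.clip(sil_miss + extra_miss, 0, 1)
        X_snp[:, j] = np.where(miss_s, np.nan, g.astype(float))
        X_sil[:, j] = np.where(miss_b, np.nan, b.astype(float))

        if mode == "low_depth":
            tag_total[j] = rng.uniform(0.9e6, 1.4e6)
            tag_unique[j] = rng.uniform(1.2e5, 2.2e5)
        else:
            tag_total[j] = max(rng.normal(2.3e6, 3.0e5), 1.6e6)
            tag_unique[j] = max(rng.normal(3.85e5, 5.0e4), 2.4e5)

    samples = [
        dataclasses.replace(
            s,
            tagcount_total=int(tag_total[j]),
            tagcount_unique=int(tag_unique[j]),
            target_qc=target_qc[j],
        )
        for j, s in enumerate(samples)
    ]

    snp = MarkerMatrix(list(snp_meta.index), [s.sample_id for s in samples], X_snp, "snp")
    silico = MarkerMatrix(
        list(silico_meta.index), [s.sample_id for s in samples], X_sil, "silico"
    )

    descriptors = _descriptors(rng, cfg, founder_ids, accessions, origin_idx, status)

    truth = SimTruth(
        sample_to_founder=sample_founder,
        accession_to_founder={acc: f for acc, f in accessions},
        lowq_samples=[(sid, lowq_mode[sid]) for sid in lowq_ids],
    )
    return SimResult(
        snp=snp,
        silico=silico,
        snp_meta=snp_meta,
        silico_meta=silico_meta,
        samples=samples,
        descriptors=descriptors,
        truth=truth,
    )


def _descriptors(rng, cfg, founder_ids, accessions, origin_idx, status):
    """Founder-level descriptor records copied to accessions, with
    configurable historical-record errors and missingness."""
    founder_desc: dict[str, dict[str, str]] = {}
    for k, f in enumerate(founder_ids):
        cid, _, _ = _ORIGINS[origin_idx[k]]
        d = {
            "biological_status": str(status[k]),
            "country": cid,
            "common_names": f"name-{k:03d}",
            "collection_date": str(int(rng.integers(1970, 1996))),
        }
        for var, vocab in _DESCRIPTOR_VOCAB.items():
            d[var] = vocab[int(rng.integers(0, len(vocab)))]
        founder_desc[f] = d

    erodable = ["common_names", "collection_date", *list(_DESCRIPTOR_VOCAB)]
    nd_able = ["collection_date", *list(_DESCRIPTOR_VOCAB)]
    rows = []
    for acc, f in accessions:
        d = dict(founder_desc[f])
        for var in erodable:
            if rng.random() < cfg.descriptor_error_rate:
                if var in _DESCRIPTOR_VOCAB:
                    vocab = [v for v in _DESCRIPTOR_VOCAB[var] if v != d[var]]
                    d[var] = vocab[int(rng.integers(0, len(vocab)))]
                elif var == "collection_date":
                    d[var] = str(int(rng.integers(1970, 1996)))
                else:
                    d[var] = f"{d[var]};alias-{acc[-3:]}"
        for var in nd_able:
            if rng.random() < cfg.descriptor_nd_rate:
                d[var] = ND
        rows.append({"accession_id": acc, **{v: d[v] for v in DESCRIPTOR_VARIABLES}})
    return pd.DataFrame(rows).set_index("accession_id")


def write_collection(result: SimResult, outdir: str | Path) -> None:
    """Emit all pipeline input CSVs plus ``truth.json``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_marker_matrix(result.snp, out / "snp_matrix.csv")
    write_marker_matrix(result.silico, out / "silico_matrix.csv")
    write_marker_meta(result.snp_meta, out / "snp_meta.csv")
    write_marker_meta(result.silico_meta, out / "silico_meta.csv")
    write_sample_meta(result.samples, out / "sample_meta.csv")
    write_descriptors(result.descriptors, out / "descriptors.csv")
    (out / "truth.json").write_text(json.dumps(result.truth.to_dict(), indent=2) + "\n")
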