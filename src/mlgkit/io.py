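"""Shared data model and CSV I/O for the redundancy-screening pipeline.

One CSV dialect per artifact (comma-separated, UTF-8, header row):

* marker matrix  — first column ``marker_id``, one column per sample;
  missing genotypes written ``NA`` (``-`` and the empty string are also
  accepted on input).
* marker metadata — ``marker_id`` plus the depth/reproducibility columns
  relevant to the marker type.
* sample metadata — documented columns, see :func:`read_sample_meta`.
* descriptors — one row per accession, ``ND`` marks "no data".
* distance matrix — square, sample ids as header row and first column;
  the corner cell stores the metric name (``ibs`` or ``jaccard``).

Native DArT report layouts (two-row SNP format etc.) are deliberately not
parsed; a converter is out of scope for this package.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "SampleMeta",
    "DistanceMatrix",
    "MISSING_TOKENS",
    "LEGAL_CODES",
    "REPLICATE_CLASSES",
    "TARGET_QC_CATEGORIES",
    "BIOLOGICAL_STATUSES",
    "DESCRIPTOR_VARIABLES",
    "ND",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_marker_meta",
    "write_marker_meta",
    "read_sample_meta",
    "write_sample_meta",
    "sample_meta_frame",
    "validate_sample_coverage",
    "read_descriptors",
    "write_descriptors",
    "read_distance_matrix",
    "write_distance_matrix",
]

#: tokens accepted as "missing" in genotype matrices (always written as NA)
MISSING_TOKENS = frozenset({"NA", "-", ""})

#: legal genotype codes per marker type (dosage of the alternate allele for
#: SNPs; presence/absence for dominant silico markers)
LEGAL_CODES = {"snp": frozenset({0, 1, 2}), "silico": frozenset({0, 1})}

REPLICATE_CLASSES = frozenset({"none", "dna", "extract", "ind"})
TARGET_QC_CATEGORIES = frozenset({"good", "downshifted", "weak"})
BIOLOGICAL_STATUSES = frozenset({"landrace", "breeding_line", "unknown"})

#: "no data" marker for descriptor tables — distinct from every category
ND = "ND"

#: the nine passport + characterization variables reviewed per MLG
DESCRIPTOR_VARIABLES = [
    "biological_status",
    "country",
    "common_names",
    "collection_date",
    "shape_central_leaf",
    "petiole_color",
    "color_first_expanded_leaf",
    "number_leaf_lobes",
    "color_root_pulp",
]

SNP_META_COLUMNS = ["avg_marker_count", "cv_marker_count", "rep_avg", "mapped"]
SILICO_META_COLUMNS = ["avg_read_depth", "cv_read_depth", "reproducibility", "mapped"]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclasses.dataclass
class MarkerMatrix:
    """A rectangular genotype table (markers x samples) for one marker type.

    ``values`` is a float array; ``NaN`` encodes a missing call.  For
    ``marker_type="snp"`` non-missing cells are alternate-allele dosages in
    {0, 1, 2}; for ``"silico"`` they are presence scores in {0, 1}.
    """

    marker_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    marker_type: str

    def __post_init__(self) -> None:
        if self.marker_type not in LEGAL_CODES:
            raise ValueError(f"unknown marker_type {self.marker_type!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"({len(self.marker_ids)} markers, {len(self.sample_ids)} samples)"
            )
        _check_unique(self.marker_ids, "marker id")
        _check_unique(self.sample_ids, "sample id")
        legal = LEGAL_CODES[self.marker_type]
        observed = self.values[~np.isnan(self.values)]
        bad = ~np.isin(observed, list(legal))
        if bad.any():
            rows, cols = np.nonzero(
                ~np.isnan(self.values) & ~np.isin(self.values, list(legal))
            )
            r, c = rows[0], cols[0]
            raise ValueError(
                f"illegal {self.marker_type} code {self.values[r, c]!r} at "
                f"marker {self.marker_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(
        self,
        marker_ids: Iterable[str] | None = None,
        sample_ids: Iterable[str] | None = None,
    ) -> "MarkerMatrix":
        """Restrict to the given markers and/or samples (order preserved)."""
        mids = list(marker_ids) if marker_ids is not None else self.marker_ids
        sids = list(sample_ids) if sample_ids is not None else self.sample_ids
        mpos = {m: i for i, m in enumerate(self.marker_ids)}
        spos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            ridx = [mpos[m] for m in mids]
        except KeyError as e:
            raise KeyError(f"marker {e.args[0]!r} not in matrix") from None
        try:
            cidx = [spos[s] for s in sids]
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None
        return MarkerMatrix(
            list(mids), list(sids), self.values[np.ix_(ridx, cidx)], self.marker_type
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.marker_ids, columns=self.sample_ids)
        df.index.name = "marker_id"
        return df


def read_marker_matrix(path: str | Path, marker_type: str) -> MarkerMatrix:
    """Read a genotype matrix CSV and validate it for ``marker_type``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a marker_id column plus at least one sample")
    if df.columns[0] != "marker_id":
        raise ValueError(f"{path}: first column must be 'marker_id', got {df.columns[0]!r}")
    if len(df) == 0:
        raise ValueError(f"{path}: no markers")
    marker_ids = [m.strip() for m in df.iloc[:, 0]]
    sample_ids = list(df.columns[1:])
    legal = LEGAL_CODES[marker_type]
    values = np.full((len(marker_ids), len(sample_ids)), np.nan)
    for j, col in enumerate(sample_ids):
        cells = df[col].str.strip()
        miss = cells.isin(MISSING_TOKENS)
        parsed = pd.to_numeric(cells[~miss], errors="coerce")
        ok = parsed.notna() & parsed.isin(list(legal))
        if not ok.all():
            i = parsed.index[~ok][0]
            raise ValueError(
                f"{path}: malformed or illegal {marker_type} value {cells[i]!r} "
                f"at marker {marker_ids[i]!r}, sample {col!r}"
            )
        values[parsed.index, j] = parsed.to_numpy()
    return MarkerMatrix(marker_ids, sample_ids, values, marker_type)


def write_marker_matrix(m: MarkerMatrix, path: str | Path) -> None:
    df = m.to_dataframe()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path)


# ---------------------------------------------------------------------------
# marker metadata


def read_marker_meta(path: str | Path, marker_type: str) -> pd.DataFrame:
    """Read per-marker metadata (depth and reproducibility statistics).

    Returns a DataFrame indexed by marker_id with the columns required for
    ``marker_type`` validated: proportions in [0, 1], depth/count and CV
    fields non-negative, ``mapped`` boolean.
    """
    df = pd.read_csv(path)
    if "marker_id" not in df.columns:
        raise ValueError(f"{path}: missing 'marker_id' column")
    df = df.set_index("marker_id")
    _check_unique(list(df.index), "marker id")
    required = SNP_META_COLUMNS if marker_type == "snp" else SILICO_META_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns for {marker_type}: {missing}")
    df = df[required].copy()
    df["mapped"] = _parse_bool(df["mapped"], path)
    prop = "rep_avg" if marker_type == "snp" else "reproducibility"
    if ((df[prop] < 0) | (df[prop] > 1)).any():
        raise ValueError(f"{path}: {prop} outside [0, 1]")
    for c in required[:2]:  # depth and cv columns
        if (df[c] < 0).any():
            raise ValueError(f"{path}: negative values in {c}")
    return df


def _parse_bool(s: pd.Series, path: str | Path) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = s.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = s[out.isna()].iloc[0]
        raise ValueError(f"{path}: unparseable boolean {bad!r} in 'mapped'")
    return out.astype(bool)


def write_marker_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, index_label="marker_id")


# ---------------------------------------------------------------------------
# sample metadata


@dataclasses.dataclass
class SampleMeta:
    """Per-sample metadata: replicate structure, library QC and provenance."""

    sample_id: str
    accession_id: str
    replicate_class: str = "none"
    replicate_group: str | None = None
    target_qc: str = "good"
    tagcount_total: int = 0
    tagcount_unique: int = 0
    region: str = "unknown"
    country: str = "UNK"
    biological_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.replicate_class not in REPLICATE_CLASSES:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate_class {self.replicate_class!r} "
                f"not one of {sorted(REPLICATE_CLASSES)}"
            )
        if self.target_qc not in TARGET_QC_CATEGORIES:
            raise ValueError(
                f"sample {self.sample_id!r}: target_qc {self.target_qc!r} "
                f"not one of {sorted(TARGET_QC_CATEGORIES)}"
            )
        if self.biological_status not in BIOLOGICAL_STATUSES:
            raise ValueError(
                f"sample {self.sample_id!r}: biological_status "
                f"{self.biological_status!r} not one of {sorted(BIOLOGICAL_STATUSES)}"
            )
        if self.replicate_group == "":
            self.replicate_group = None
        if self.replicate_class != "none" and not self.replicate_group:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate_class "
                f"{self.replicate_class!r} requires a replicate_group"
            )
        if self.tagcount_total < 0 or self.tagcount_unique < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative tag count")


SAMPLE_META_COLUMNS = [f.name for f in dataclasses.fields(SampleMeta)]


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sample metadata columns: {missing}")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                accession_id=row["accession_id"],
                replicate_class=row["replicate_class"],
                replicate_group=row["replicate_group"] or None,
                target_qc=row["target_qc"],
                tagcount_total=int(row["tagcount_total"]),
                tagcount_unique=int(row["tagcount_unique"]),
                region=row["region"],
                country=row["country"],
                biological_status=row["biological_status"],
            )
        )
    _check_unique([m.sample_id for m in metas], "sample id")
    return metas


def write_sample_meta(metas: Sequence[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        d = dataclasses.asdict(m)
        d["replicate_group"] = d["replicate_group"] or ""
        rows.append(d)
    pd.DataFrame(rows, columns=SAMPLE_META_COLUMNS).to_csv(path, index=False)


def sample_meta_frame(metas: Sequence[SampleMeta]) -> pd.DataFrame:
    """Sample metadata as a DataFrame indexed by sample_id."""
    df = pd.DataFrame([dataclasses.asdict(m) for m in metas])
    return df.set_index("sample_id")


def validate_sample_coverage(
    matrix: MarkerMatrix, metas: Sequence[SampleMeta]
) -> list[str]:
    """Return matrix samples absent from the metadata (empty list = covered)."""
    known = {m.sample_id for m in metas}
    return [s for s in matrix.sample_ids if s not in known]


# ---------------------------------------------------------------------------
# descriptors


def read_descriptors(path: str | Path) -> pd.DataFrame:
    """Read the per-accession descriptor table; empty cells become ``ND``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "accession_id" not in df.columns:
        raise ValueError(f"{path}: missing 'accession_id' column")
    df = df.set_index("accession_id")
    _check_unique(list(df.index), "accession id")
    missing = [c for c in DESCRIPTOR_VARIABLES if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing descriptor columns: {missing}")
    df = df[DESCRIPTOR_VARIABLES].copy()
    return df.replace("", ND)


def write_descriptors(d: pd.DataFrame, path: str | Path) -> None:
    d.to_csv(path, index_label="accession_id")


# ---------------------------------------------------------------------------
# distance matrices


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric pairwise sample-distance matrix with labels.

    ``degenerate_pairs`` flags sample pairs whose distance is a sentinel
    (no co-called loci for IBS, no shared presences for Jaccard) rather
    than a measurement.
    """

    sample_ids: list[str]
    values: np.ndarray
    metric: str
    degenerate_pairs: list[tuple[str, str]] = dataclasses.field(default_factory=list)

    SYMMETRY_TOL = 1e-12

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.metric not in ("ibs", "jaccard"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        _check_unique(self.sample_ids, "sample id")
        if np.abs(np.diag(self.values)).max(initial=0.0) > self.SYMMETRY_TOL:
            raise ValueError("distance matrix diagonal is not zero")
        if n and np.abs(self.values - self.values.T).max() > self.SYMMETRY_TOL:
            raise ValueError("distance matrix is not symmetric")
        if n and ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("distance entries must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def loc(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.values[i, j])

    def subset(self, sample_ids: Iterable[str]) -> "DistanceMatrix":
        sids = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sids]
        keep = set(sids)
        degen = [(a, b) for a, b in self.degenerate_pairs if a in keep and b in keep]
        return DistanceMatrix(sids, self.values[np.ix_(idx, idx)], self.metric, degen)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n_samples, k=1)
        return self.values[iu]


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a square CSV; the corner cell records the metric name."""
    # re-validate so a mutated matrix cannot be silently persisted
    DistanceMatrix(dm.sample_ids, dm.values, dm.metric, dm.degenerate_pairs)
    df = pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.sample_ids)
    df.index.name = dm.metric
    df.to_csv(path, float_format="%.12f")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    metric = str(df.index.name).strip().lower()
    if metric not in ("ibs", "jaccard"):
        raise ValueError(
            f"{path}: corner cell must name the metric (ibs or jaccard), got {metric!r}"
        )
    sample_ids = [str(s) for s in df.index]
    if sample_ids != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column sample ids disagree")
    values = df.to_numpy(dtype=float)
    if np.abs(values - values.T).max(initial=0.0) > DistanceMatrix.SYMMETRY_TOL:
        raise ValueError(f"{path}: matrix is not symmetric")
    return DistanceMatrix(sample_ids, values, metric)


# ---------------------------------------------------------------------------
# small JSON helper used by reports and the CLI


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
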