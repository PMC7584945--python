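"""Core data model: OTU tables, abundance transforms, alpha diversity, Bray–Curtis.

Everything downstream (community comparison, marker discovery, dysbiosis
ratios, co-occurrence networks) operates on the containers defined here.
Conventions:

* counts are non-negative integers, rows = samples, columns = OTUs;
* relative abundance ("unit" scale) is the default substrate; parts-per-million
  ("ppm", rows sum to 1e6) is used by the LDA effect-size stage;
* Shannon diversity is in nats so that Pielou evenness J = H / ln(S) is exact;
* Bray–Curtis is a dissimilarity in [0, 1], not a metric.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Group",
    "Timepoint",
    "OtuTable",
    "SampleMetadata",
    "AbundanceProfile",
    "AlphaDiversity",
    "DistanceMatrix",
    "FormatError",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "to_relative",
    "sqrt_transform",
    "alpha_diversity",
    "alpha_diversity_table",
    "bray_curtis",
    "distance_matrix",
]


class FormatError(ValueError):
    """Raised when an input file or table violates the format contract."""


class Group(str, enum.Enum):
    """Experimental arm: healthy control, injury-only, or injury + MSC."""

    NC = "NC"
    CCL4 = "CCl4"
    MSC = "MSC"


class Timepoint(str, enum.Enum):
    H48 = "48h"
    W1 = "1w"
    W2 = "2w"


#: Cohort label shorthand used throughout ("M48", "C1W", ... and "NC").
_COHORT_PREFIX = {Group.CCL4: "C", Group.MSC: "M"}
_COHORT_SUFFIX = {Timepoint.H48: "48", Timepoint.W1: "1W", Timepoint.W2: "2W"}


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design metadata.

    The study design has seven cohorts: NC sampled at 48 h only, and the
    CCl4 / MSC arms each sampled at 48 h, 1 week and 2 weeks.
    """

    sample_id: str
    group: Group
    timepoint: Timepoint

    def __post_init__(self) -> None:
        if self.group is Group.NC and self.timepoint is not Timepoint.H48:
            raise ValueError(
                f"sample {self.sample_id!r}: NC controls exist only at 48h "
                f"(got {self.timepoint.value})"
            )

    @property
    def cohort(self) -> str:
        """Cohort label, e.g. ``M48``, ``C1W``; plain ``NC`` for controls."""
        if self.group is Group.NC:
            return "NC"
        return _COHORT_PREFIX[self.group] + _COHORT_SUFFIX[self.timepoint]


@dataclass
class OtuTable:
    """Integer count matrix (samples x OTUs) with optional taxonomy.

    Parameters
    ----------
    sample_ids, otu_ids
        Unique row / column identifiers.
    counts
        Non-negative integer array of shape ``(n_samples, n_otus)``.
    taxonomy
        Optional map from OTU id to a lineage string.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        n_s, n_o = self.counts.shape
        if n_s < 1 or n_o < 1:
            raise FormatError("table must have at least one sample and one OTU")
        if len(self.sample_ids) != n_s or len(self.otu_ids) != n_o:
            raise FormatError("id lists do not match counts shape")
        if len(set(self.sample_ids)) != n_s:
            raise FormatError("duplicate sample ids")
        if len(set(self.otu_ids)) != n_o:
            raise FormatError("duplicate OTU ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise FormatError("counts must be non-negative")
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.otu_ids)
            if unknown:
                raise FormatError(f"taxonomy for unknown OTUs: {sorted(unknown)[:5]}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def subset_samples(self, keep: list[str]) -> "OtuTable":
        """Return a new table restricted to ``keep`` (order preserved)."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [idx[s] for s in keep]
        return OtuTable(list(keep), list(self.otu_ids), self.counts[rows], self.taxonomy)


class Scale(str, enum.Enum):
    UNIT = "unit"  # rows sum to 1
    PPM = "ppm"  # rows sum to 1e6
    SQRT = "sqrt"  # square-root of a unit profile; rows not normalized


_SCALE_TOTAL = {Scale.UNIT: 1.0, Scale.PPM: 1e6}


@dataclass
class AbundanceProfile:
    """Real-valued abundance matrix sharing the axes of an :class:`OtuTable`."""

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray
    scale: Scale = Scale.UNIT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("abundances must be non-negative")
        if self.scale in _SCALE_TOTAL:
            total = _SCALE_TOTAL[self.scale]
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, total, rtol=1e-9, atol=0):
                raise ValueError(f"rows must sum to {total} on scale {self.scale.value}")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]


@dataclass(frozen=True)
class AlphaDiversity:
    """Observed richness, Shannon diversity (nats) and Pielou evenness.

    ``pielou`` is ``None`` (undefined) for single-species samples rather than
    0, so that group means are not silently biased.
    """

    richness: int
    shannon: float
    pielou: float | None


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with ids; zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# File I/O (TSV dialect: UTF-8, tab-delimited, '#' comment lines ignored)
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0, header=0)
    except Exception as exc:  # malformed file
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"{path}: empty table")
    return df


def _check_header_unique(path) -> None:
    # pandas silently mangles duplicate column names; inspect the raw header
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")[1:]
            if len(cols) != len(set(cols)):
                raise FormatError(f"{path}: duplicate ids in header")
            return
    raise FormatError(f"{path}: empty table")


def read_otu_table(
    path,
    orientation: str = "samples_as_rows",
    taxonomy: dict[str, str] | None = None,
) -> OtuTable:
    """Read a tab-separated count matrix.

    ``orientation`` declares whether rows of the file are samples
    (``"samples_as_rows"``) or OTUs (``"otus_as_rows"``); the returned table
    always has samples as rows.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    _check_header_unique(path)
    df = _read_tsv_matrix(path)
    if orientation == "otus_as_rows":
        df = df.T
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate ids")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric cell")
    if np.any(~np.isfinite(arr.astype(float))):
        raise FormatError(f"{path}: non-finite cell")
    if np.any(arr < 0):
        raise FormatError(f"{path}: negative count")
    return OtuTable(
        [str(s) for s in df.index],
        [str(o) for o in df.columns],
        arr,
        taxonomy=taxonomy,
    )


def write_otu_table(t: OtuTable, path) -> None:
    t.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> list[SampleMetadata]:
    """Read sample metadata TSV with columns sample_id, group, timepoint."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "group", "timepoint"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: metadata needs columns {sorted(required)}")
    out = []
    for rec in df.itertuples(index=False):
        try:
            out.append(SampleMetadata(rec.sample_id, Group(rec.group), Timepoint(rec.timepoint)))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if len({m.sample_id for m in out}) != len(out):
        raise FormatError(f"{path}: duplicate sample ids")
    return out


def write_metadata(metadata: list[SampleMetadata], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "group": [m.group.value for m in metadata],
            "timepoint": [m.timepoint.value for m in metadata],
            "cohort": [m.cohort for m in metadata],
        }
    ).to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> dict[str, str]:
    """Read a two-column TSV mapping otu_id -> lineage string."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: taxonomy needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def to_relative(t: OtuTable, scale: Scale | str = Scale.UNIT) -> AbundanceProfile:
    """Row-normalize counts to relative abundance (unit or ppm scale)."""
    scale = Scale(scale)
    if scale not in _SCALE_TOTAL:
        raise ValueError(f"normalization target must be unit or ppm, not {scale.value}")
    sums = t.counts.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        bad = [t.sample_ids[i] for i in zero]
        raise ValueError(f"all-zero sample(s): {bad}")
    vals = t.counts / sums[:, None] * _SCALE_TOTAL[scale]
    return AbundanceProfile(list(t.sample_ids), list(t.otu_ids), vals, scale)


def sqrt_transform(p: AbundanceProfile) -> AbundanceProfile:
    """Elementwise square root of a unit-scale profile (not re-normalized)."""
    if p.scale is not Scale.UNIT:
        raise ValueError("sqrt_transform expects a unit-scale profile")
    return AbundanceProfile(list(p.sample_ids), list(p.otu_ids), np.sqrt(p.values), Scale.SQRT)


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(counts_row: np.ndarray) -> AlphaDiversity:
    """Richness, Shannon (nats) and Pielou evenness of one sample's counts."""
    c = np.asarray(counts_row, dtype=float)
    if c.ndim != 1 or np.any(c < 0):
        raise ValueError("counts_row must be a 1-D non-negative vector")
    pos = c[c > 0]
    if pos.size == 0:
        raise ValueError("all-zero sample has no diversity")
    richness = int(pos.size)
    p = pos / pos.sum()
    shannon = float(-(p * np.log(p)).sum()) if richness > 1 else 0.0
    shannon = max(shannon, 0.0)
    pielou = shannon / math.log(richness) if richness >= 2 else None
    return AlphaDiversity(richness, shannon, pielou)


def alpha_diversity_table(t: OtuTable) -> pd.DataFrame:
    """Per-sample alpha diversity, one row per sample."""
    recs = []
    for sid, row in zip(t.sample_ids, t.counts):
        a = alpha_diversity(row)
        recs.append({"sample_id": sid, "richness": a.richness, "shannon": a.shannon,
                     "pielou": a.pielou if a.pielou is not None else np.nan})
    return pd.DataFrame(recs).set_index("sample_id")


# ---------------------------------------------------------------------------
# Bray–Curtis
# ---------------------------------------------------------------------------

def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray–Curtis dissimilarity  sum|x-y| / sum(x+y)  in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray–Curtis undefined for two all-zero vectors")
    return float(np.abs(x - y).sum() / denom)


def distance_matrix(p: AbundanceProfile) -> DistanceMatrix:
    """All-pairs Bray–Curtis distance matrix over samples."""
    if len(p.sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    if np.any(p.values.sum(axis=1) == 0):
        raise ValueError("all-zero sample in profile")
    d = squareform(pdist(p.values, metric="braycurtis"))
    return DistanceMatrix(list(p.sample_ids), d)
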