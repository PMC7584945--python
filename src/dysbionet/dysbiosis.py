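"""Liver-injury dysbiosis ratio (LIDR).

The LIDR of a sample is the ratio of the summed relative abundance of
disease-associated marker OTUs (the set associated with the injured arm at
baseline) to that of health-associated marker OTUs (the set associated with
healthy controls at baseline):

    LIDR = sum_{k in D} p_k / sum_{k in H} p_k

Marker sets D and H are discovered once, on the baseline (48 h) injured and
control cohorts, by the effect-size screen in :mod:`dysbionet.lefse`; the
ratio is then tracked per sample across all cohorts and timepoints. Because
it is a ratio of relative abundances it is invariant to sequencing depth, and
group contrasts are run on log10-transformed values by default.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AbundanceProfile, OtuTable, SampleMetadata, Scale, to_relative
from .lefse import MarkerSets, associate_otus
from .compare import TestResult, bonferroni, one_way_anova, t_test

__all__ = [
    "DysbiosisScore",
    "define_marker_sets",
    "lidr",
    "lidr_table",
    "cohort_summary",
    "compare_lidr",
]


@dataclass(frozen=True)
class DysbiosisScore:
    sample_id: str
    lidr: float  # inf when the denominator is zero and no pseudocount is set
    numerator_mass: float
    denominator_mass: float

    @property
    def finite(self) -> bool:
        return math.isfinite(self.lidr)


def define_marker_sets(
    t: OtuTable,
    metadata: list[SampleMetadata],
    seed: int | None = None,
    **lefse_kwargs,
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Discover (disease, health) marker sets on the baseline cohorts.

    Restricts the table to the injured and control cohorts at 48 h, runs the
    effect-size screen with the arm as the class label, and returns the
    disease-associated set D, the health-associated set H, and the full
    screen table. Raises if either set comes back empty: the ratio is
    undefined without both.
    """
    by_id = {m.sample_id: m for m in metadata}
    baseline = [s for s in t.sample_ids if by_id[s].cohort in ("C48", "NC")]
    if not baseline:
        raise ValueError("baseline cohorts (C48, NC) absent from table")
    sub = t.subset_samples(baseline)
    classes = [by_id[s].group.value for s in baseline]
    if len(set(classes)) != 2:
        raise ValueError("both baseline cohorts (C48 and NC) are required")
    markers, table = associate_otus(sub, classes, seed=seed, **lefse_kwargs)
    disease, health = markers["CCl4"], markers["NC"]
    if not disease or not health:
        raise ValueError(
            "LIDR undefined: baseline screen produced an empty marker set "
            f"(disease n={len(disease)}, health n={len(health)})"
        )
    return disease, health, table


def lidr(
    values: np.ndarray,
    otu_ids: list[str],
    disease: set[str],
    health: set[str],
    sample_id: str = "",
    pseudocount: float = 0.0,
) -> DysbiosisScore:
    """LIDR of one abundance row. ``pseudocount`` (same units as the row) is
    added to both masses when set; with pseudocount 0 a zero denominator
    yields an infinite, flagged score."""
    if not disease or not health:
        raise ValueError("marker sets must be non-empty")
    present = set(otu_ids)
    missing = sorted((disease | health) - present)
    if missing:
        raise KeyError(f"marker OTUs absent from table: {missing[:10]}")
    col = {o: i for i, o in enumerate(otu_ids)}
    v = np.asarray(values, dtype=float)
    num = float(v[[col[o] for o in sorted(disease)]].sum()) + pseudocount
    den = float(v[[col[o] for o in sorted(health)]].sum()) + pseudocount
    if den == 0:
        warnings.warn(f"sample {sample_id!r}: zero health-marker mass, LIDR infinite", stacklevel=2)
        return DysbiosisScore(sample_id, math.inf, num, den)
    return DysbiosisScore(sample_id, num / den, num, den)


def lidr_table(
    t_or_profile: OtuTable | AbundanceProfile,
    disease: set[str],
    health: set[str],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-sample LIDR for a whole table (one row per sample)."""
    if isinstance(t_or_profile, OtuTable):
        prof = to_relative(t_or_profile, Scale.UNIT)
    else:
        prof = t_or_profile
    recs = []
    for sid, row in zip(prof.sample_ids, prof.values):
        s = lidr(row, prof.otu_ids, disease, health, sample_id=sid, pseudocount=pseudocount)
        recs.append(
            {"sample_id": sid, "lidr": s.lidr,
             "numerator_mass": s.numerator_mass, "denominator_mass": s.denominator_mass}
        )
    return pd.DataFrame(recs).set_index("sample_id")


def cohort_summary(scores_by_cohort: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean +/- SE summary, one row per cohort (SE = sd / sqrt(n))."""
    recs = []
    for cohort, vals in scores_by_cohort.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        n = len(v)
        sd = float(np.std(v, ddof=1)) if n > 1 else float("nan")
        recs.append(
            {"cohort": cohort, "n": n, "mean_lidr": float(v.mean()) if n else float("nan"),
             "se": sd / math.sqrt(n) if n > 1 else float("nan")}
        )
    return pd.DataFrame(recs)


def compare_lidr(
    scores_by_cohort: dict[str, np.ndarray], transform: str = "log10"
) -> pd.DataFrame:
    """Overall one-way ANOVA plus Bonferroni-adjusted pairwise Welch t-tests
    across the given cohorts (typically the three timepoints of one arm).

    Infinite scores are dropped with a warning before testing; the transform
    (default log10, natural for ratios) is applied inside each test.
    """
    clean: dict[str, np.ndarray] = {}
    for cohort, vals in scores_by_cohort.items():
        v = np.asarray(vals, dtype=float)
        finite = v[np.isfinite(v)]
        if len(finite) < len(v):
            warnings.warn(f"cohort {cohort}: dropped {len(v) - len(finite)} infinite LIDR(s)",
                          stacklevel=2)
        if len(finite) < 2:
            raise ValueError(f"cohort {cohort}: need >= 2 finite scores")
        clean[cohort] = finite
    names = list(clean)
    rows = []
    res = one_way_anova([clean[c] for c in names], transform=transform)
    rows.append({"comparison": " vs ".join(names), "method": res.method,
                 "statistic": res.statistic, "p": res.p, "p_adjusted": np.nan})
    pairs = list(itertools.combinations(names, 2))
    for a, b in pairs:
        res = t_test(clean[a], clean[b], transform=transform)
        rows.append({"comparison": f"{a} vs {b}", "method": res.method,
                     "statistic": res.statistic, "p": res.p,
                     "p_adjusted": bonferroni(res.p, len(pairs))})
    return pd.DataFrame(rows)
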