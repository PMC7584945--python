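"""Marker-OTU discovery: Kruskal–Wallis screen + bootstrapped LDA effect size.

The procedure mirrors the classic LEfSe recipe: abundances scaled to parts
per million, a Kruskal–Wallis test (alpha = 0.05) screens features for any
class effect, and surviving features receive an effect size from repeated
(default 30) linear-discriminant fits on random two-thirds subsamples of
each class. For one bootstrap the effect of feature k is

    e_k = ( |w_k| * d  +  |m1_k - m2_k| ) / 2

where w is the unit-norm Fisher discriminant of the two classes (within-class
covariance regularized with eps*I, eps = 1e-6 * trace/p), d = |w . (m1 - m2)|
is the projected class-mean gap, and m1, m2 are the class means. The reported
score is log10(1 + mean over bootstraps), so scores live on the familiar
0–6 log10 scale, and a feature passes at the default threshold 2.0.

Designs with more than two classes are handled one-vs-rest; a feature is
assigned to the class where its one-vs-rest score is maximal among classes in
which it is enriched (class mean above the rest-mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import OtuTable, Scale, to_relative

__all__ = ["EffectSizeResult", "MarkerSets", "kw_test", "lda_effect_size", "associate_otus"]

KW_ALPHA = 0.05
LDA_THRESHOLD = 2.0
N_BOOT = 30
SUBSAMPLE_FRAC = 2.0 / 3.0


@dataclass(frozen=True)
class EffectSizeResult:
    otu_id: str
    enriched_class: str | None
    kw_p: float
    lda_score: float
    passed: bool


@dataclass
class MarkerSets:
    """Per-class marker OTU sets; pairwise disjoint by construction."""

    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cls, s in self.sets.items():
            if seen & s:
                raise ValueError(f"marker sets overlap at class {cls!r}")
            seen |= s

    def __getitem__(self, cls: str) -> set[str]:
        return self.sets.get(cls, set())

    @property
    def all_markers(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


def kw_test(values, classes) -> float:
    """Kruskal–Wallis p-value (tie-corrected, chi-square approximation).

    All values tied across all samples -> p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    uniq = np.unique(classes)
    if len(uniq) < 2:
        raise ValueError("need >= 2 classes")
    groups = [values[classes == c] for c in uniq]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every class needs >= 2 samples")
    if np.all(values == values[0]):
        return 1.0
    return float(stats.kruskal(*groups).pvalue)


def _fisher_effect(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Per-feature effect from one regularized Fisher-LDA fit of two classes."""
    m1 = X1.mean(axis=0)
    m2 = X2.mean(axis=0)
    n1, n2 = len(X1), len(X2)
    p = X1.shape[1]
    Sw = ((n1 - 1) * np.cov(X1, rowvar=False) + (n2 - 1) * np.cov(X2, rowvar=False)) / (
        n1 + n2 - 2
    )
    Sw = np.atleast_2d(Sw)
    tr = np.trace(Sw)
    eps = 1e-6 * tr / p if tr > 0 else 1e-6
    Sw = Sw + eps * np.eye(p)
    w = np.linalg.solve(Sw, m1 - m2)
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.abs(m1 - m2) / 2.0
    w = w / norm
    d = abs(float(w @ (m1 - m2)))
    return (np.abs(w) * d + np.abs(m1 - m2)) / 2.0


def lda_effect_size(
    X: np.ndarray,
    classes,
    n_boot: int = N_BOOT,
    subsample_frac: float = SUBSAMPLE_FRAC,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrapped LDA effect size of every column of ``X`` (ppm scale).

    Returns ``(scores, enriched)``: log10-scale scores and, per feature, the
    index (0/1) of the class with the larger full-data mean. ``classes`` must
    contain exactly two labels. Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    classes = np.asarray(classes)
    uniq = sorted(set(classes.tolist()), key=str)
    if len(uniq) != 2:
        raise ValueError("lda_effect_size is two-class; use associate_otus for more")
    idx1 = np.flatnonzero(classes == uniq[0])
    idx2 = np.flatnonzero(classes == uniq[1])
    rng = np.random.default_rng(seed)
    acc = np.zeros(X.shape[1])
    used = 0
    for _ in range(n_boot):
        k1 = int(round(subsample_frac * len(idx1)))
        k2 = int(round(subsample_frac * len(idx2)))
        if k1 < 3 or k2 < 3:
            continue
        s1 = rng.choice(idx1, size=k1, replace=False)
        s2 = rng.choice(idx2, size=k2, replace=False)
        acc += _fisher_effect(X[s1], X[s2])
        used += 1
    if used == 0:
        raise ValueError("all bootstraps skipped: classes too small (need >= 3 after subsampling)")
    scores = np.log10(1.0 + acc / used)
    enriched = (X[idx2].mean(axis=0) > X[idx1].mean(axis=0)).astype(int)
    return scores, enriched


def associate_otus(
    t: OtuTable,
    classes,
    alpha: float = KW_ALPHA,
    lda_threshold: float = LDA_THRESHOLD,
    n_boot: int = N_BOOT,
    subsample_frac: float = SUBSAMPLE_FRAC,
    seed: int | None = None,
) -> tuple[MarkerSets, pd.DataFrame]:
    """Full marker-discovery pipeline on an OTU table.

    ``classes`` is one label per sample (row). Returns the per-class marker
    sets and the full results table (otu_id, enriched_class, kw_p, lda_score,
    passed). Multi-class designs are scored one-vs-rest. An empty result is a
    valid outcome (warned, not raised).
    """
    classes = np.asarray([str(c) for c in classes])
    if len(classes) != t.n_samples:
        raise ValueError("classes length does not match table")
    uniq = sorted(set(classes.tolist()))
    if len(uniq) < 2:
        raise ValueError("need >= 2 classes")
    X = to_relative(t, Scale.PPM).values

    kw_p = np.array([kw_test(X[:, j], classes) for j in range(t.n_otus)])
    keep = np.flatnonzero(kw_p < alpha)
    scores = np.zeros(t.n_otus)
    enriched = np.array([None] * t.n_otus, dtype=object)

    if keep.size:
        Xk = X[:, keep]
        if len(uniq) == 2:
            sc, enr = lda_effect_size(Xk, classes, n_boot, subsample_frac, seed)
            scores[keep] = sc
            enriched[keep] = np.array(uniq, dtype=object)[enr]
        else:
            per_class = np.full((len(uniq), keep.size), -np.inf)
            for ci, cls in enumerate(uniq):
                ovr = np.where(classes == cls, cls, "__rest__")
                sc, enr = lda_effect_size(
                    Xk, ovr, n_boot, subsample_frac, None if seed is None else seed + ci
                )
                # only classes where the feature is enriched (enr points at the
                # focal class, which sorts after "__rest__")
                focal = 1 if sorted(["__rest__", cls])[1] == cls else 0
                per_class[ci] = np.where(enr == focal, sc, -np.inf)
            best = per_class.argmax(axis=0)
            best_score = per_class.max(axis=0)
            ok = np.isfinite(best_score)
            scores[keep[ok]] = best_score[ok]
            enriched[keep[ok]] = np.array(uniq, dtype=object)[best[ok]]

    passed = (kw_p < alpha) & (scores >= lda_threshold) & (enriched != None)  # noqa: E711
    table = pd.DataFrame(
        {
            "otu_id": t.otu_ids,
            "enriched_class": enriched,
            "kw_p": kw_p,
            "lda_score": scores,
            "passed": passed,
        }
    )
    sets = {
        cls: set(table.loc[table.passed & (table.enriched_class == cls), "otu_id"])
        for cls in uniq
    }
    if not any(sets.values()):
        warnings.warn("no OTU passed the effect-size screen", stacklevel=2)
    return MarkerSets({c: s for c, s in sets.items() if s}), table
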