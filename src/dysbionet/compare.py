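"""Community-level comparisons: PERMANOVA, SIMPER, PAM clustering, and the
univariate tests (Welch t, one-way ANOVA, Bonferroni) used for diversity and
dysbiosis-ratio contrasts.

PERMANOVA follows the one-way sums-of-squares decomposition on a distance
matrix (Anderson's pseudo-F): with n samples in a groups,

    SS_total   = (1/n)   sum_{i<j}      d_ij^2
    SS_within  = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    pseudo-F   = (SS_between / (a-1)) / (SS_within / (n-a))

and the p-value comes from label permutations: sampled permutations use the
+1-corrected estimate p = (#{F_perm >= F_obs} + 1)/(n_perm + 1); exhaustive
mode enumerates every distinct assignment of samples to groups of the
observed sizes and reports the exact proportion.

SIMPER decomposes the average between-group Bray–Curtis dissimilarity into
additive per-OTU contributions: for each between-group sample pair (i, j),
OTU k contributes |y_ik - y_jk| / sum_k (y_ik + y_jk), and contributions are
averaged over pairs, so they sum exactly to the mean between-group
dissimilarity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceProfile, DistanceMatrix, Scale, sqrt_transform

__all__ = [
    "PermanovaResult",
    "SimperResult",
    "ClusteringResult",
    "KSelection",
    "TestResult",
    "permanova",
    "simper",
    "pam_cluster",
    "silhouette_samples",
    "choose_k",
    "t_test",
    "one_way_anova",
    "bonferroni",
]


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r2: float
    p: float
    n_perm: int
    exhaustive: bool


def _encode_labels(labels) -> tuple[np.ndarray, list]:
    labels = list(labels)
    uniq = sorted(set(labels), key=str)
    codes = np.array([uniq.index(l) for l in labels])
    return codes, uniq


def _batch_pseudo_F(D2: np.ndarray, perms: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for each row of label codes in ``perms`` (n_perm x n)."""
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ssw = np.zeros(perms.shape[0])
    for g in range(n_groups):
        m = (perms == g).astype(float)
        n_g = m[0].sum()  # group sizes identical across permutations
        ssw += np.einsum("pi,ij,pj->p", m, D2, m) / 2.0 / n_g
    ssb = ss_total - ssw
    a = n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (a - 1)) / (ssw / (n - a))
    F[ssw == 0] = np.inf
    return F


def _exhaustive_assignments(codes: np.ndarray, cap: int):
    """Yield every distinct assignment of positions to groups of the observed
    sizes (group labels kept distinct)."""
    n = len(codes)
    sizes = np.bincount(codes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(int(s))
    if total > cap:
        return None
    groups = len(sizes)

    def rec(positions: tuple, g: int, current: np.ndarray):
        if g == groups - 1:
            out = current.copy()
            out[list(positions)] = g
            yield out
            return
        for chosen in itertools.combinations(positions, int(sizes[g])):
            nxt = current.copy()
            nxt[list(chosen)] = g
            remaining = tuple(p for p in positions if p not in set(chosen))
            yield from rec(remaining, g + 1, nxt)

    return rec(tuple(range(n)), 0, np.empty(n, dtype=int))


def permanova(
    d: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
    cap: int = 100_000,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    With ``exhaustive=True`` and at most ``cap`` distinct assignments, the
    exact permutation p-value over all assignments is reported instead of the
    sampled one.
    """
    codes, uniq = _encode_labels(labels)
    if len(codes) != d.n:
        raise ValueError("labels length does not match distance matrix")
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    D2 = d.d**2
    n = d.n
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    if ss_total <= 0:
        raise ValueError("degenerate distance matrix: no variation")
    F_obs = float(_batch_pseudo_F(D2, codes[None, :], len(uniq))[0])
    ssw_obs = 0.0
    for g in range(len(uniq)):
        idx = np.flatnonzero(codes == g)
        sub = D2[np.ix_(idx, idx)]
        ssw_obs += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    r2 = float(np.clip((ss_total - ssw_obs) / ss_total, 0.0, 1.0))

    tol = 1e-12
    if exhaustive:
        gen = _exhaustive_assignments(codes, cap)
        if gen is not None:
            count = hits = 0
            for assign in gen:
                Fp = float(_batch_pseudo_F(D2, assign[None, :], len(uniq))[0])
                count += 1
                if Fp >= F_obs - tol:
                    hits += 1
            return PermanovaResult(F_obs, r2, hits / count, count, True)
        # too many assignments: fall through to sampling
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    F_perm = _batch_pseudo_F(D2, perms, len(uniq))
    p = (int(np.sum(F_perm >= F_obs - tol)) + 1) / (n_perm + 1)
    return PermanovaResult(F_obs, r2, p, n_perm, False)


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

@dataclass
class SimperResult:
    table: pd.DataFrame  # otu_id, contribution, percent, cumulative_percent
    overall_dissimilarity: float


def simper(p: AbundanceProfile, labels, transform: str = "sqrt") -> SimperResult:
    """Per-OTU decomposition of mean between-group Bray–Curtis dissimilarity.

    ``transform='sqrt'`` square-roots the unit-scale profile first (the
    conventional overall transformation); ``'none'`` uses it as-is.
    """
    codes, uniq = _encode_labels(labels)
    if len(uniq) != 2:
        raise ValueError(f"SIMPER requires exactly two groups, got {len(uniq)}")
    if transform == "sqrt":
        p = sqrt_transform(p)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    Y = p.values
    A = Y[codes == 0]
    B = Y[codes == 1]
    # pairwise between-group terms: (nA, nB, K)
    diff = np.abs(A[:, None, :] - B[None, :, :])
    denom = (A[:, None, :] + B[None, :, :]).sum(axis=2)  # (nA, nB)
    contrib = (diff / denom[:, :, None]).mean(axis=(0, 1))  # (K,)
    overall = float(contrib.sum())
    percent = contrib / overall * 100.0 if overall > 0 else np.zeros_like(contrib)
    df = pd.DataFrame(
        {"otu_id": p.otu_ids, "contribution": contrib, "percent": percent}
    ).sort_values(["contribution", "otu_id"], ascending=[False, True], ignore_index=True)
    df["cumulative_percent"] = df["percent"].cumsum()
    return SimperResult(df, overall)


# ---------------------------------------------------------------------------
# PAM (k-medoids) and silhouette-based model selection
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    k: int
    medoids: list[str]
    labels: np.ndarray  # cluster index per sample, aligned with d.ids
    avg_silhouette: float
    silhouettes: np.ndarray


def _assign(d: np.ndarray, medoid_idx: list[int]) -> np.ndarray:
    # nearest medoid; ties go to the lower medoid position (argmin convention)
    return np.argmin(d[:, medoid_idx], axis=1)


def pam_cluster(d: DistanceMatrix, k: int, seed: int | None = None) -> ClusteringResult:
    """Partition Around Medoids via the classic BUILD + SWAP descent.

    Deterministic: BUILD greedily seeds medoids, SWAP applies the single best
    strictly-improving (medoid, candidate) exchange until none remains; ties
    break toward the lowest index. ``seed`` is accepted for interface
    uniformity but the procedure involves no randomness.
    """
    n = d.n
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n_samples (k={k}, n={n})")
    D = d.d
    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        cur = D[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    # SWAP
    medoids = sorted(medoids)
    cost = D[:, medoids].min(axis=1).sum()
    improved = True
    while improved:
        improved = False
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + medoids[mi + 1:] + [h]
                new_cost = D[:, trial].min(axis=1).sum()
                delta = cost - new_cost
                if delta > best[0] + 1e-12:
                    best = (delta, m, h)
        if best[1] is not None:
            medoids = sorted(set(medoids) - {best[1]} | {best[2]})
            cost -= best[0]
            improved = True
    labels = _assign(D, medoids)
    sil = silhouette_samples(d, labels)
    return ClusteringResult(
        k=k,
        medoids=[d.ids[m] for m in medoids],
        labels=labels,
        avg_silhouette=float(sil.mean()),
        silhouettes=sil,
    )


def silhouette_samples(d: DistanceMatrix, labels: np.ndarray) -> np.ndarray:
    """Silhouette s(i) = (b_i - a_i)/max(a_i, b_i) from a distance matrix.

    Members of singleton clusters, and points with a = b = 0 (all-identical
    inputs), get silhouette 0.
    """
    labels = np.asarray(labels)
    D = d.d
    uniq = np.unique(labels)
    s = np.zeros(d.n)
    for i in range(d.n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            continue
        a = D[i, own].sum() / (n_own - 1)
        others = [c for c in uniq if c != labels[i]]
        if not others:  # a single populated cluster: silhouette undefined -> 0
            continue
        b = min(D[i, labels == c].mean() for c in others)
        m = max(a, b)
        s[i] = (b - a) / m if m > 0 else 0.0
    return s


@dataclass
class KSelection:
    k_best: int
    silhouettes: dict[int, float]  # k -> average silhouette
    results: dict[int, ClusteringResult]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": list(self.silhouettes), "avg_silhouette": list(self.silhouettes.values())}
        )


def choose_k(d: DistanceMatrix, k_range=range(2, 7), seed: int | None = None) -> KSelection:
    """Run PAM for each k and pick the average-silhouette argmax (ties ->
    smallest k). The full silhouette-vs-k table is kept so secondary optima
    remain visible."""
    ks = [k for k in k_range if 2 <= k < d.n]
    if not ks:
        raise ValueError("empty or invalid k range")
    results = {k: pam_cluster(d, k, seed=seed) for k in ks}
    sils = {k: results[k].avg_silhouette for k in ks}
    k_best = max(ks, key=lambda k: (sils[k], -k))
    return KSelection(k_best, sils, results)


# ---------------------------------------------------------------------------
# Univariate tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    transform: str = "none"
    p_adjusted: float | None = None


def _apply_transform(arrs: list[np.ndarray], transform: str) -> list[np.ndarray]:
    if transform == "none":
        return [np.asarray(a, dtype=float) for a in arrs]
    if transform == "log10":
        out = []
        for a in arrs:
            a = np.asarray(a, dtype=float)
            if np.any(a <= 0):
                raise ValueError("log10 transform requires strictly positive values")
            out.append(np.log10(a))
        return out
    raise ValueError(f"unknown transform {transform!r}")


def t_test(x, y, transform: str = "none") -> TestResult:
    """Welch two-sample t-test (unequal variances)."""
    x, y = _apply_transform([x, y], transform)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return TestResult(0.0, 1.0, "welch_t", transform)
        return TestResult(np.inf if np.mean(x) > np.mean(y) else -np.inf, 0.0, "welch_t", transform)
    stat, p = stats.ttest_ind(x, y, equal_var=False)
    return TestResult(float(stat), float(p), "welch_t", transform)


def one_way_anova(groups, transform: str = "none") -> TestResult:
    """Standard one-way ANOVA F-test across >= 2 groups."""
    arrs = _apply_transform(list(groups), transform)
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.var(a) == 0 for a in arrs) and len({float(np.mean(a)) for a in arrs}) == 1:
        return TestResult(0.0, 1.0, "anova", transform)
    stat, p = stats.f_oneway(*arrs)
    return TestResult(float(stat), float(p), "anova", transform)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value min(1, m*p)."""
    if not 0 <= p <= 1 or m < 1:
        raise ValueError("need p in [0,1] and m >= 1")
    return min(1.0, m * p)
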