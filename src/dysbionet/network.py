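"""Ensemble co-occurrence network inference and gatekeeper (fragmentation)
analysis.

The network stage follows the CoNet ensemble recipe. Five association
measures are computed between every pair of sufficiently prevalent OTUs on
relative abundances: Pearson and Spearman correlation, Bray–Curtis
dissimilarity, symmetrized Kullback–Leibler divergence, and mutual
information on rank-binned abundances. Each measure proposes its strongest
candidate edges (top-N most positive and most negative correlations; for
dissimilarities the smallest values propose co-presence and the largest
mutual exclusion). Candidate edges receive per-measure p-values from a
ReBoot-style permutation null — each OTU's abundances are permuted
independently across samples and every sample is renormalized, so purely
compositional correlations survive in the null and are discounted — and the
per-measure p-values are merged with Brown's method, whose chi-square
moments are corrected with the empirical covariance of the measures' null
statistics. Edges are kept when the Benjamini–Hochberg q-value passes and at
least ``min_support`` measures propose the edge with a consistent sign.

Gatekeepers are nodes whose removal fragments the network more than chance.
Fragmentation of a graph with N nodes and components of sizes n_c is

    F = 1 - sum_c n_c (n_c - 1) / (N (N - 1)),

the fraction of node pairs that cannot reach each other. The null
distribution re-scores the same node's removal in (default 10,000)
degree-preserving rewirings of the observed network (double-edge swaps, at
least 10x|E| swaps each); the p-value is the fraction of null fragmentation
scores at or above the observed one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .core import AbundanceProfile, OtuTable, Scale, to_relative

__all__ = [
    "MEASURES",
    "CoNetwork",
    "GatekeeperResult",
    "pair_score",
    "candidate_edges",
    "reboot_pvalue",
    "merge_pvalues",
    "build_network",
    "hub_ranking",
    "fragmentation",
    "gatekeeper_test",
    "gatekeeper_scan",
]

MEASURES = ("pearson", "spearman", "bray_curtis", "kld", "mutual_information")
#: measures whose sign carries over directly to the edge sign
_SIGNED = ("pearson", "spearman")
#: dissimilarities: small = co-presence (+), large = exclusion (-)
_DISSIM = ("bray_curtis", "kld")

KLD_PSEUDOCOUNT = 1e-6
MI_BINS = 4


# ---------------------------------------------------------------------------
# Pairwise association measures (vectorized over all OTU pairs)
# ---------------------------------------------------------------------------

def _rank_rows(data: np.ndarray) -> np.ndarray:
    return stats.rankdata(data, axis=1)


def _corr_matrix(data: np.ndarray) -> np.ndarray:
    sd = data.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(data)
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    return c


def _kld_matrix(data: np.ndarray, pseudocount: float = KLD_PSEUDOCOUNT) -> np.ndarray:
    P = data + pseudocount
    P = P / P.sum(axis=1, keepdims=True)
    L = np.log(P)
    a = (P * L).sum(axis=1)
    cross = P @ L.T
    return 0.5 * (a[:, None] + a[None, :] - cross - cross.T)


def _mi_matrix(data: np.ndarray, nbins: int = MI_BINS) -> np.ndarray:
    """Mutual information (nats) on equal-frequency rank bins."""
    n_rows, n = data.shape
    order = np.argsort(data, axis=1, kind="stable")
    pos = np.empty_like(order)
    rows = np.arange(n_rows)[:, None]
    pos[rows, order] = np.arange(n)[None, :]
    bins = (pos * nbins) // n  # equal-frequency bin index per observation
    ind = [(bins == b).astype(np.float64) for b in range(nbins)]
    marg = np.stack([m.sum(axis=1) for m in ind], axis=1)  # (n_rows, nbins)
    mi = np.zeros((n_rows, n_rows))
    for a in range(nbins):
        for b in range(nbins):
            joint = ind[a] @ ind[b].T  # (n_rows, n_rows) counts
            expected = marg[:, a][:, None] * marg[:, b][None, :] / n
            with np.errstate(divide="ignore", invalid="ignore"):
                term = joint / n * np.log(joint / expected)
            mi += np.where(joint > 0, term, 0.0)
    return np.maximum(mi, 0.0)


def _score_matrix(data: np.ndarray, measure: str) -> np.ndarray:
    """All-pairs score matrix; ``data`` is OTUs x samples of abundances."""
    if measure == "pearson":
        return _corr_matrix(data)
    if measure == "spearman":
        return _corr_matrix(_rank_rows(data))
    if measure == "bray_curtis":
        return squareform(pdist(data, metric="braycurtis"))
    if measure == "kld":
        return _kld_matrix(data)
    if measure == "mutual_information":
        return _mi_matrix(data)
    raise ValueError(f"unknown measure {measure!r}")


def pair_score(x, y, measure: str) -> float:
    """Association score of one pair of abundance vectors.

    Returns NaN (undefined) for correlation measures on constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("vectors must be 1-D, equal length >= 4")
    m = _score_matrix(np.vstack([x, y]), measure)
    return float(m[0, 1])


# ---------------------------------------------------------------------------
# Candidate edges
# ---------------------------------------------------------------------------

def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, 1)


def candidate_edges(
    p: AbundanceProfile, measure: str, top_n: int = 1000
) -> pd.DataFrame:
    """Strongest candidate edges under one measure, with provisional sign.

    Signed measures contribute their ``top_n`` most positive (+) and most
    negative (-) pairs; dissimilarities their smallest (+, co-presence) and
    largest (-, exclusion); mutual information its largest, signed by the
    Spearman sign of the same pair. Fewer pairs than ``top_n`` returns all
    (with a warning).
    """
    data = p.values.T
    iu = _pair_index(data.shape[0])
    scores = _score_matrix(data, measure)[iu]
    spear = _score_matrix(data, "spearman")[iu] if measure == "mutual_information" else None
    rows = _candidates_from_scores(scores, measure, top_n, spear)
    n_pairs = len(scores)
    if n_pairs < top_n:
        warnings.warn(f"only {n_pairs} pairs available (top_n={top_n})", stacklevel=2)
    out = pd.DataFrame(
        {
            "otu_a": [p.otu_ids[iu[0][k]] for k in rows["idx"]],
            "otu_b": [p.otu_ids[iu[1][k]] for k in rows["idx"]],
            "score": rows["score"],
            "sign": rows["sign"],
        }
    )
    return out


def _candidates_from_scores(scores, measure, top_n, spearman_scores=None) -> dict:
    """Pick candidate pair indices and signs from a condensed score vector."""
    valid = np.flatnonzero(np.isfinite(scores))
    s = scores[valid]
    idx: list[int] = []
    sign: list[int] = []
    if measure in _SIGNED:
        pos = valid[s > 0]
        neg = valid[s < 0]
        pos = pos[np.argsort(-scores[pos], kind="stable")][:top_n]
        neg = neg[np.argsort(scores[neg], kind="stable")][:top_n]
        idx = [*pos, *neg]
        sign = [1] * len(pos) + [-1] * len(neg)
    elif measure in _DISSIM:
        order = valid[np.argsort(s, kind="stable")]
        lo = order[:top_n]
        hi = order[::-1][:top_n]
        hi = hi[~np.isin(hi, lo)]  # tiny inputs: a pair cannot be both
        idx = [*lo, *hi]
        sign = [1] * len(lo) + [-1] * len(hi)
    elif measure == "mutual_information":
        top = valid[np.argsort(-s, kind="stable")][:top_n]
        sp = spearman_scores[top]
        idx = list(top)
        sign = [1 if (np.isnan(v) or v >= 0) else -1 for v in sp]
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return {"idx": np.asarray(idx, dtype=int), "score": scores[np.asarray(idx, dtype=int)]
            if len(idx) else np.array([]), "sign": np.asarray(sign, dtype=int)}


# ---------------------------------------------------------------------------
# ReBoot permutation null
# ---------------------------------------------------------------------------

def _reboot_table(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One null table: permute each OTU column independently, renormalize rows."""
    perm = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        perm[:, j] = values[rng.permutation(n), j]
    sums = perm.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return perm / sums


def _null_scores(
    values: np.ndarray,
    measures: tuple[str, ...],
    pair_idx: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Null score draws, shape (n_perm, n_pairs) per measure.

    ``pair_idx`` indexes into the condensed upper-triangle pair order.
    """
    out = {m: np.empty((n_perm, len(pair_idx)), dtype=np.float32) for m in measures}
    n_otus = values.shape[1]
    iu = _pair_index(n_otus)
    for t in range(n_perm):
        null = _reboot_table(values, rng).T
        for m in measures:
            out[m][t] = _score_matrix(null, m)[iu][pair_idx]
    return out


def _two_sided_p(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Two-sided permutation p centered at the null mean, +1-corrected.

    ``obs``: (n_pairs,); ``null``: (n_perm, n_pairs). NaN-safe: an undefined
    observed score gets p = NaN.
    """
    n_perm = null.shape[0]
    mean = np.nanmean(null, axis=0)
    dev = np.abs(null - mean[None, :])
    obs_dev = np.abs(obs - mean)
    hits = np.nansum(dev >= obs_dev[None, :] - 1e-12, axis=0)
    p = (hits + 1) / (n_perm + 1)
    return np.where(np.isfinite(obs_dev), p, np.nan)


def reboot_pvalue(
    pair: tuple[str, str],
    measure: str,
    p: AbundanceProfile,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """Two-sided ReBoot permutation p-value for one pair under one measure."""
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable p-values", stacklevel=2)
    ids = p.otu_ids
    try:
        i, j = ids.index(pair[0]), ids.index(pair[1])
    except ValueError as exc:
        raise KeyError(f"pair {pair} not in profile") from exc
    iu = _pair_index(len(ids))
    flat = np.flatnonzero((iu[0] == min(i, j)) & (iu[1] == max(i, j)))
    obs = _score_matrix(p.values.T, measure)[min(i, j), max(i, j)]
    rng = np.random.default_rng(seed)
    null = _null_scores(p.values, (measure,), flat, n_perm, rng)[measure]
    return float(_two_sided_p(np.array([obs]), null)[0])


# ---------------------------------------------------------------------------
# P-value merging
# ---------------------------------------------------------------------------

def merge_pvalues(ps, method: str = "fisher", null_pvalues: np.ndarray | None = None) -> float:
    """Combine per-measure p-values into one.

    ``fisher``: -2 sum ln p ~ chi2(2m) under independence. ``brown``: the same
    statistic referred to a scaled chi-square whose moments are estimated from
    ``null_pvalues`` (n_draws x m per-measure p-values of null permutation
    draws), so dependence between measures is absorbed.
    """
    ps = np.asarray([p for p in np.atleast_1d(ps) if np.isfinite(p)], dtype=float)
    if ps.size == 0:
        raise ValueError("no valid p-values to merge")
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if ps.size == 1:
        return float(ps[0])
    X = -2.0 * np.log(ps).sum()
    if method == "fisher":
        return float(stats.chi2.sf(X, 2 * ps.size))
    if method == "brown":
        if null_pvalues is None:
            raise ValueError("brown merging needs null_pvalues draws")
        null_pvalues = np.asarray(null_pvalues, dtype=float)
        Xt = -2.0 * np.log(np.clip(null_pvalues, 1e-300, 1.0)).sum(axis=1)
        E = Xt.mean()
        V = Xt.var(ddof=1)
        if V <= 0 or E <= 0:
            return float(stats.chi2.sf(X, 2 * ps.size))
        f = 2.0 * E * E / V
        c = V / (2.0 * E)
        return float(stats.chi2.sf(X / c, f))
    raise ValueError(f"unknown merge method {method!r}")


def _null_pseudo_pvalues(null: np.ndarray) -> np.ndarray:
    """Two-sided pseudo p-value of each null draw within its own null
    distribution (columns are pairs); used for Brown moment estimation."""
    n_perm = null.shape[0]
    dev = np.abs(null - np.nanmean(null, axis=0, keepdims=True))
    order = np.argsort(np.argsort(-dev, axis=0, kind="stable"), axis=0)
    # rank 0 = most extreme -> p = 1/n_perm ... least extreme -> p = 1
    return (order + 1) / n_perm


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

@dataclass
class CoNetwork:
    """Undirected signed co-occurrence network over OTUs."""

    nodes: list[str]
    edges: pd.DataFrame  # otu_a, otu_b, sign, support, merged_p, q, per-measure scores
    params: dict = field(default_factory=dict)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for rec in self.edges.itertuples(index=False):
            g.add_edge(rec.otu_a, rec.otu_b, sign=int(rec.sign), q=float(rec.q))
        return g

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_network(
    t: OtuTable | AbundanceProfile,
    prevalence_min: float = 1 / 3,
    top_n: int = 1000,
    n_perm: int = 1000,
    q_max: float = 0.05,
    min_support: int = 2,
    seed: int | None = None,
    merge_method: str = "brown",
    measures: tuple[str, ...] = MEASURES,
) -> CoNetwork:
    """Infer the ensemble co-occurrence network of an OTU table.

    Pipeline: prevalence filter -> per-measure candidate edges -> ReBoot
    permutation p-values -> Brown/Fisher merge -> Benjamini–Hochberg across
    edges -> keep q <= ``q_max`` with >= ``min_support`` sign-consistent
    proposing measures. Deterministic given ``seed``. An empty network is a
    valid outcome.
    """
    if isinstance(t, OtuTable):
        if t.n_samples < 5:
            raise ValueError("need >= 5 samples for network inference")
        prevalence = (t.counts > 0).mean(axis=0)
        keep = np.flatnonzero(prevalence >= prevalence_min)
        if keep.size < 2:
            raise ValueError("fewer than 2 OTUs pass the prevalence filter")
        sub = OtuTable(list(t.sample_ids), [t.otu_ids[i] for i in keep], t.counts[:, keep])
        prof = to_relative(sub, Scale.UNIT)
    else:
        prof = t
        if len(prof.sample_ids) < 5:
            raise ValueError("need >= 5 samples for network inference")
    ids = prof.otu_ids
    data = prof.values.T
    n_otus = len(ids)
    iu = _pair_index(n_otus)

    # observed scores and per-measure proposals
    obs = {m: _score_matrix(data, m)[iu] for m in measures}
    spear = obs["spearman"] if "spearman" in obs else _score_matrix(data, "spearman")[iu]
    proposals: dict[int, dict[str, int]] = {}
    for m in measures:
        cand = _candidates_from_scores(obs[m], m, top_n, spear)
        for k, sg in zip(cand["idx"], cand["sign"]):
            proposals.setdefault(int(k), {})[m] = int(sg)
    if not proposals:
        return CoNetwork(list(ids), _empty_edges(measures), _params_dict(locals()))

    pair_idx = np.array(sorted(proposals), dtype=int)
    rng = np.random.default_rng(seed)
    null = _null_scores(prof.values, measures, pair_idx, n_perm, rng)

    pm = {m: _two_sided_p(obs[m][pair_idx], null[m]) for m in measures}
    null_pp = {m: _null_pseudo_pvalues(null[m]) for m in measures}

    merged = np.empty(len(pair_idx))
    for e in range(len(pair_idx)):
        valid = [m for m in measures if np.isfinite(pm[m][e])]
        ps = [pm[m][e] for m in valid]
        if not valid:
            merged[e] = np.nan
            continue
        if merge_method == "brown" and len(valid) > 1:
            draws = np.column_stack([null_pp[m][:, e] for m in valid])
            merged[e] = merge_pvalues(ps, "brown", null_pvalues=draws)
        else:
            merged[e] = merge_pvalues(ps, "fisher")

    ok = np.isfinite(merged)
    q = np.full(len(pair_idx), np.nan)
    if ok.any():
        q[ok] = multipletests(merged[ok], method="fdr_bh")[1]

    rows = []
    for e, k in enumerate(pair_idx):
        props = proposals[int(k)]
        signs = set(props.values())
        consistent = len(signs) == 1
        support = len(props)
        if not consistent or support < min_support:
            continue
        if not np.isfinite(q[e]) or q[e] > q_max:
            continue
        i, j = int(iu[0][k]), int(iu[1][k])
        row = {
            "otu_a": ids[i], "otu_b": ids[j], "sign": signs.pop(), "support": support,
            "merged_p": merged[e], "q": q[e],
        }
        for m in measures:
            row[f"score_{m}"] = obs[m][k]
            row[f"p_{m}"] = pm[m][e]
        rows.append(row)
    edges = pd.DataFrame(rows) if rows else _empty_edges(measures)
    edges = edges.sort_values(["q", "otu_a", "otu_b"], ignore_index=True) if len(edges) else edges
    params = {
        "prevalence_min": prevalence_min, "top_n": top_n, "n_perm": n_perm,
        "q_max": q_max, "min_support": min_support, "seed": seed,
        "merge_method": merge_method,
    }
    return CoNetwork(list(ids), edges, params)


def _empty_edges(measures) -> pd.DataFrame:
    cols = ["otu_a", "otu_b", "sign", "support", "merged_p", "q"]
    cols += [f"score_{m}" for m in measures] + [f"p_{m}" for m in measures]
    return pd.DataFrame(columns=cols)


def _params_dict(loc) -> dict:
    return {k: loc[k] for k in ("prevalence_min", "top_n", "n_perm", "q_max", "min_support", "seed")
            if k in loc}


def hub_ranking(net: CoNetwork | nx.Graph, top_n: int = 10) -> pd.DataFrame:
    """Top OTUs by degree (most correlations); ties break by node id."""
    g = net.graph() if isinstance(net, CoNetwork) else net
    ranked = sorted(g.degree, key=lambda kv: (-kv[1], str(kv[0])))
    ranked = [(n, d) for n, d in ranked if d > 0][:top_n]
    return pd.DataFrame(ranked, columns=["otu_id", "degree"])


# ---------------------------------------------------------------------------
# Fragmentation and gatekeepers
# ---------------------------------------------------------------------------

def fragmentation(g: nx.Graph) -> float:
    """Fraction of node pairs not connected by any path (Borgatti's F)."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("fragmentation needs >= 2 nodes")
    reach = sum(len(c) * (len(c) - 1) for c in nx.connected_components(g))
    return 1.0 - reach / (n * (n - 1))


def _fragmentation_edges(n_nodes: int, edges: np.ndarray, drop: int) -> float:
    """Fragmentation of the graph minus node ``drop`` via union-find."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        if a == drop or b == drop:
            continue
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    sizes: dict[int, int] = {}
    for v in range(n_nodes):
        if v == drop:
            continue
        r = find(v)
        sizes[r] = sizes.get(r, 0) + 1
    n = n_nodes - 1
    reach = sum(s * (s - 1) for s in sizes.values())
    return 1.0 - reach / (n * (n - 1))


def _double_edge_swaps(
    edges: np.ndarray, n_swaps: int, rng: np.random.Generator, max_tries: int | None = None
) -> np.ndarray:
    """Degree-preserving rewiring by repeated double-edge swaps.

    Attempts are capped, so graphs admitting no legal swap (e.g. cliques)
    return unchanged instead of looping forever.
    """
    edges = edges.copy()
    e = len(edges)
    if e < 2:
        raise ValueError("need >= 2 edges to rewire")
    present = {(min(a, b), max(a, b)) for a, b in edges}
    max_tries = max_tries if max_tries is not None else 20 * n_swaps
    swaps = tries = 0
    while swaps < n_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(e), rng.integers(e)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(2):
            c, d = d, c
        # propose (a, c) and (b, d)
        if a == c or b == d:
            continue
        e1 = (min(a, c), max(a, c))
        e2 = (min(b, d), max(b, d))
        if e1 in present or e2 in present:
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(c, d), max(c, d)))
        present.add(e1)
        present.add(e2)
        edges[i] = e1
        edges[j] = e2
        swaps += 1
    return edges


def _gnm_edges(n_nodes: int, n_edges: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform simple graph with the given node and edge counts."""
    all_pairs = n_nodes * (n_nodes - 1) // 2
    if n_edges > all_pairs:
        raise ValueError("too many edges for a simple graph")
    chosen = rng.choice(all_pairs, size=n_edges, replace=False)
    iu = np.triu_indices(n_nodes, 1)
    return np.column_stack([iu[0][chosen], iu[1][chosen]])


@dataclass(frozen=True)
class GatekeeperResult:
    node: str
    f_before: float
    f_after: float
    delta_f: float
    null_count: int
    n_null: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def gatekeeper_test(
    net: CoNetwork | nx.Graph,
    node,
    n_null: int = 10_000,
    seed: int | None = None,
    null_model: str = "degree",
    swap_factor: int = 10,
) -> GatekeeperResult:
    """Permutation test of whether removing ``node`` fragments the network
    more than expected in randomized networks.

    ``null_model='degree'`` (default) rewires the observed network with
    degree-preserving double-edge swaps (>= ``swap_factor`` x |E| swaps per
    null draw), keeping node identity so the same node is removed at the same
    degree; ``'gnm'`` only preserves the node and edge counts. The one-sided
    p counts null fragmentation scores >= the observed one (+1-corrected).
    """
    g = net.graph() if isinstance(net, CoNetwork) else net
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    if g.number_of_edges() < 2:
        raise ValueError("network too small to rewire (|E| < 2)")
    nodes = sorted(g.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(index[a], index[b]) for a, b in g.edges], dtype=np.int64)
    drop = index[node]
    n = len(nodes)

    f_before = fragmentation(g)
    f_after = _fragmentation_edges(n, edges, drop)
    rng = np.random.default_rng(seed)
    n_swaps = swap_factor * len(edges)
    hits = 0
    for _ in range(n_null):
        if null_model == "degree":
            null_edges = _double_edge_swaps(edges, n_swaps, rng)
        elif null_model == "gnm":
            null_edges = _gnm_edges(n, len(edges), rng)
        else:
            raise ValueError(f"unknown null model {null_model!r}")
        if _fragmentation_edges(n, null_edges, drop) >= f_after - 1e-12:
            hits += 1
    p = (hits + 1) / (n_null + 1)
    return GatekeeperResult(str(node), f_before, f_after, f_after - f_before, hits, n_null, p)


def gatekeeper_scan(
    net: CoNetwork | nx.Graph,
    n_null: int = 10_000,
    seed: int | None = None,
    null_model: str = "degree",
    nodes=None,
) -> pd.DataFrame:
    """Gatekeeper test for every (or the given) node; one row per node."""
    g = net.graph() if isinstance(net, CoNetwork) else net
    targets = list(nodes) if nodes is not None else sorted(g.nodes, key=str)
    ss = np.random.SeedSequence(seed).spawn(len(targets))
    rows = []
    for node, sub_seed in zip(targets, ss):
        r = gatekeeper_test(g, node, n_null=n_null,
                            seed=int(sub_seed.generate_state(1)[0] % (2**31)),
                            null_model=null_model)
        rows.append({"node": r.node, "f_before": r.f_before, "f_after": r.f_after,
                     "delta_f": r.delta_f, "p": r.p, "significant": r.significant})
    return pd.DataFrame(rows).sort_values("delta_f", ascending=False, ignore_index=True)
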