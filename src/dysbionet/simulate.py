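"""Synthetic study generator.

Emulates the 7-cohort murine liver-injury design (one healthy-control cohort
at 48 h; injury-only and MSC-treated arms each sampled at 48 h / 1 week /
2 weeks, n = 6 mice per cohort) so every downstream stage can be exercised
and validated against planted truth without the deposited sequencing reads.

The count model is a logistic-normal / Dirichlet-multinomial hybrid:

1. a log-normal baseline composition over OTUs, fixed per study seed;
2. per-cohort multiplicative fold-changes on planted disease- and
   health-associated OTU sets (these drive the dysbiosis-ratio trajectory:
   falling in the MSC arm, rising in the injury arm);
3. a per-sample log-normal perturbation of every OTU (Gaussian copula), with
   planted pairwise correlations for the network stage;
4. a Dirichlet draw around the perturbed composition (overdispersion) and a
   multinomial read draw at the configured depth.

The Dirichlet concentration is parameterized per OTU: the Dirichlet parameter
vector is ``concentration * n_otus * composition``, so an OTU of average
abundance has concentration ~50 under the default. Sample-to-sample
overdispersion is dominated by the explicit log-normal layer, which is what
carries the planted correlation structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import Group, OtuTable, SampleMetadata, Timepoint

__all__ = [
    "SynthSpec",
    "PlantedTruth",
    "generate_study",
    "generate_samples",
    "default_study_spec",
    "marker_benchmark_spec",
    "correlation_benchmark_spec",
    "make_graph_fixture",
]

#: Cohorts of the study design, in canonical order.
COHORTS: list[tuple[str, Group, Timepoint]] = [
    ("NC", Group.NC, Timepoint.H48),
    ("C48", Group.CCL4, Timepoint.H48),
    ("C1W", Group.CCL4, Timepoint.W1),
    ("C2W", Group.CCL4, Timepoint.W2),
    ("M48", Group.MSC, Timepoint.H48),
    ("M1W", Group.MSC, Timepoint.W1),
    ("M2W", Group.MSC, Timepoint.W2),
]

#: Default fold-change schedule for the disease-associated OTU set, chosen so
#: the dysbiosis ratio falls over time under MSC treatment and rises without
#: it; health-associated OTUs get the reciprocal fold.
DEFAULT_DISEASE_FOLDS: dict[str, float] = {
    "NC": 1.0,
    "C48": 1.5, "C1W": 3.0, "C2W": 6.0,
    "M48": 6.0, "M1W": 1.5, "M2W": 1.0,
}


@dataclass
class SynthSpec:
    """Parameters of the synthetic study.

    ``disease_folds`` maps cohort label -> fold applied to every OTU in
    ``disease_otus``; ``health_folds`` defaults to the reciprocal schedule.
    ``correlated_pairs`` are (otu_a, otu_b, rho) triples realized through the
    per-sample log-normal layer (Gaussian copula), whose spread is
    ``log_noise_sd``.
    """

    n_otus: int = 150
    depth: int = 30_000
    n_per_cohort: int = 6
    base_log_mean: float = 0.0
    base_log_sd: float = 1.0
    dirichlet_concentration: float = 50.0
    log_noise_sd: float = 0.5
    disease_otus: tuple[str, ...] = ()
    health_otus: tuple[str, ...] = ()
    disease_folds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DISEASE_FOLDS))
    health_folds: dict[str, float] | None = None  # None -> reciprocal of disease
    correlated_pairs: tuple[tuple[str, str, float], ...] = ()
    log_mean_shift: dict[str, float] | None = None  # per-OTU baseline log-mean offset
    seed: int = 0

    @property
    def otu_ids(self) -> list[str]:
        return [f"OTU{i + 1:04d}" for i in range(self.n_otus)]

    def validate(self) -> None:
        if self.n_otus < 2 or self.depth < 1 or self.n_per_cohort < 1:
            raise ValueError("n_otus, depth and n_per_cohort must be positive")
        if self.dirichlet_concentration <= 0 or self.log_noise_sd < 0:
            raise ValueError("dirichlet_concentration must be > 0 and log_noise_sd >= 0")
        ids = set(self.otu_ids)
        d, h = set(self.disease_otus), set(self.health_otus)
        if d & h:
            raise ValueError("disease and health OTU sets must be disjoint")
        if (d | h) - ids:
            raise ValueError(f"marker OTUs not in table: {sorted((d | h) - ids)[:5]}")
        for folds in (self.disease_folds, self.health_folds or {}):
            if any(f <= 0 for f in folds.values()):
                raise ValueError("fold-changes must be > 0")
        for a, b, rho in self.correlated_pairs:
            if a not in ids or b not in ids:
                raise ValueError(f"correlated pair ({a}, {b}) references unknown OTU")
            if a == b:
                raise ValueError("correlated pair must involve two distinct OTUs")
            if not -1 < rho < 1:
                raise ValueError("|rho| must be < 1")
        if self.log_mean_shift and set(self.log_mean_shift) - ids:
            raise ValueError("log_mean_shift references unknown OTUs")
        if self.depth < self.n_otus:
            warnings.warn("depth below n_otus: most OTUs will be unobserved", stacklevel=2)


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside generated data."""

    fold_changes: dict[str, dict[str, float]]  # cohort -> otu_id -> fold
    disease_otus: tuple[str, ...]
    health_otus: tuple[str, ...]
    correlated_pairs: tuple[tuple[str, str, float], ...]
    bridge_nodes: tuple = ()


def default_study_spec(seed: int = 0, **overrides) -> SynthSpec:
    """Spec mirroring the study conditions: 7 cohorts x 6 mice, 15 planted
    disease- and 15 health-associated OTUs, a few correlated background pairs."""
    n_otus = overrides.pop("n_otus", 150)
    if n_otus < 40:
        raise ValueError("the default study layout needs n_otus >= 40 "
                         "(30 marker OTUs + correlated background pairs)")
    ids = [f"OTU{i + 1:04d}" for i in range(n_otus)]
    disease = tuple(ids[:15])
    health = tuple(ids[15:30])
    pairs = tuple((ids[30 + 2 * k], ids[31 + 2 * k], 0.8) for k in range(5))
    return SynthSpec(
        n_otus=n_otus,
        disease_otus=disease,
        health_otus=health,
        correlated_pairs=pairs,
        seed=seed,
        **overrides,
    )


def marker_benchmark_spec(seed: int = 0, fold: float = 4.0) -> SynthSpec:
    """Two-cohort benchmark for the marker-discovery screen.

    100 OTUs with a realistic rank-abundance shape: 20 planted markers in the
    moderately-abundant range (10 up ``fold``-times in the injured cohort, 10
    up in controls), 75 rare background OTUs in the single-digit-count tail,
    and 5 dominant ballast taxa carrying most of the reads. Ten mice per
    cohort at depth 5e4, modest biological noise.
    """
    ids = [f"OTU{i + 1:04d}" for i in range(100)]
    planted, background, ballast = ids[:20], ids[20:95], ids[95:]
    shift = {o: 6.0 for o in ballast}
    shift.update({o: -2.5 for o in background})
    shift.update({o: 0.3 for o in planted})
    return SynthSpec(
        n_otus=100, depth=50_000, n_per_cohort=10,
        base_log_sd=0.5, log_noise_sd=0.2, dirichlet_concentration=1000.0,
        disease_otus=tuple(ids[:10]), health_otus=tuple(ids[10:20]),
        disease_folds={"C48": fold}, health_folds={"NC": fold},
        log_mean_shift=shift, seed=seed,
    )


def correlation_benchmark_spec(
    seed: int = 0, n_pairs: int = 20, rho: float = 0.9, n_samples: int = 30
) -> SynthSpec:
    """Benchmark for co-occurrence inference: 100 OTUs, ``n_pairs`` disjoint
    planted correlations, no group structure; draw with
    :func:`generate_samples`."""
    ids = [f"OTU{i + 1:04d}" for i in range(100)]
    pairs = tuple((ids[2 * k], ids[2 * k + 1], rho) for k in range(n_pairs))
    return SynthSpec(
        n_otus=100, depth=100_000, n_per_cohort=n_samples,
        base_log_sd=1.0, log_noise_sd=1.0,
        correlated_pairs=pairs, seed=seed,
    )


def _cohort_folds(spec: SynthSpec, cohort: str) -> np.ndarray:
    folds = np.ones(spec.n_otus)
    idx = {o: i for i, o in enumerate(spec.otu_ids)}
    df = spec.disease_folds.get(cohort, 1.0)
    if spec.health_folds is not None:
        hf = spec.health_folds.get(cohort, 1.0)
    else:
        hf = 1.0 / df
    for o in spec.disease_otus:
        folds[idx[o]] = df
    for o in spec.health_otus:
        folds[idx[o]] = hf
    return folds


def _correlated_noise(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """One per-OTU N(0, sd^2) draw with the planted pairwise correlations."""
    e = rng.standard_normal(spec.n_otus)
    z = e.copy()
    idx = {o: i for i, o in enumerate(spec.otu_ids)}
    for a, b, rho in spec.correlated_pairs:
        i, j = idx[a], idx[b]
        z[j] = rho * e[i] + np.sqrt(1.0 - rho * rho) * e[j]
    return spec.log_noise_sd * z


def generate_study(spec: SynthSpec) -> tuple[OtuTable, list[SampleMetadata], PlantedTruth]:
    """Generate counts, metadata and planted truth for the 7-cohort design.

    Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = rng.lognormal(spec.base_log_mean, spec.base_log_sd, spec.n_otus)
    if spec.log_mean_shift:
        idx = {o: i for i, o in enumerate(spec.otu_ids)}
        for o, shift in spec.log_mean_shift.items():
            base[idx[o]] *= np.exp(shift)
    base /= base.sum()

    sample_ids: list[str] = []
    metadata: list[SampleMetadata] = []
    rows = []
    fold_truth: dict[str, dict[str, float]] = {}
    for cohort, group, tp in COHORTS:
        folds = _cohort_folds(spec, cohort)
        fold_truth[cohort] = {
            o: float(folds[i]) for i, o in enumerate(spec.otu_ids) if folds[i] != 1.0
        }
        for k in range(spec.n_per_cohort):
            sid = f"{cohort}_{k + 1}"
            sample_ids.append(sid)
            metadata.append(SampleMetadata(sid, group, tp))
            comp = base * folds * np.exp(_correlated_noise(spec, rng))
            comp /= comp.sum()
            theta = rng.dirichlet(spec.dirichlet_concentration * spec.n_otus * comp)
            rows.append(rng.multinomial(spec.depth, theta))

    taxonomy = {
        o: f"k__Bacteria; f__Family{i % 20:02d}; g__Genus{i:04d}"
        for i, o in enumerate(spec.otu_ids)
    }
    table = OtuTable(sample_ids, spec.otu_ids, np.asarray(rows), taxonomy)
    truth = PlantedTruth(
        fold_changes=fold_truth,
        disease_otus=tuple(spec.disease_otus),
        health_otus=tuple(spec.health_otus),
        correlated_pairs=tuple(spec.correlated_pairs),
    )
    return table, metadata, truth


def generate_samples(spec: SynthSpec, n_samples: int | None = None) -> tuple[OtuTable, PlantedTruth]:
    """Draw one homogeneous cohort (baseline composition, no fold-changes).

    Used for fixtures without group structure, e.g. network benchmarks and
    null calibration; planted correlations are honoured. Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    n = n_samples if n_samples is not None else spec.n_per_cohort
    rng = np.random.default_rng(spec.seed)
    base = rng.lognormal(spec.base_log_mean, spec.base_log_sd, spec.n_otus)
    if spec.log_mean_shift:
        idx = {o: i for i, o in enumerate(spec.otu_ids)}
        for o, shift in spec.log_mean_shift.items():
            base[idx[o]] *= np.exp(shift)
    base /= base.sum()
    rows = []
    for _ in range(n):
        comp = base * np.exp(_correlated_noise(spec, rng))
        comp /= comp.sum()
        theta = rng.dirichlet(spec.dirichlet_concentration * spec.n_otus * comp)
        rows.append(rng.multinomial(spec.depth, theta))
    table = OtuTable([f"S_{k + 1}" for k in range(n)], spec.otu_ids, np.asarray(rows))
    truth = PlantedTruth(
        fold_changes={}, disease_otus=(), health_otus=(),
        correlated_pairs=tuple(spec.correlated_pairs),
    )
    return table, truth


# ---------------------------------------------------------------------------
# Graph fixtures for the fragmentation / gatekeeper stage
# ---------------------------------------------------------------------------

def _connected_gnp(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    for _ in range(1000):
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return g
    raise ValueError(f"could not draw a connected G({n}, {p}) graph")


def make_graph_fixture(kind: str, **params) -> tuple[nx.Graph, PlantedTruth]:
    """Deterministic graph fixtures with known bridge (gatekeeper) nodes.

    Kinds
    -----
    ``barbell``: two cliques of size ``m`` (default 5) joined through a single
    bridge node; ``erdos_renyi``: G(n, p); ``planted_bridge``: two connected
    G(n, p) blobs joined through one cut vertex.
    """
    truth_kwargs = dict(fold_changes={}, disease_otus=(), health_otus=(), correlated_pairs=())
    if kind == "barbell":
        m = int(params.get("m", 5))
        if m < 3:
            raise ValueError("barbell needs cliques of size >= 3")
        g = nx.barbell_graph(m, 1)  # nodes 0..m-1, bridge m, m+1..2m
        return g, PlantedTruth(bridge_nodes=(m,), **truth_kwargs)
    if kind == "erdos_renyi":
        n, p = int(params["n"]), float(params["p"])
        seed = int(params.get("seed", 0))
        if n < 2 or not 0 <= p <= 1:
            raise ValueError("need n >= 2 and p in [0, 1]")
        return nx.gnp_random_graph(n, p, seed=seed), PlantedTruth(**truth_kwargs)
    if kind == "planted_bridge":
        n = int(params.get("n", 10))
        p = float(params.get("p", 0.5))
        seed = int(params.get("seed", 0))
        if n < 3:
            raise ValueError("blobs need n >= 3")
        rng = np.random.default_rng(seed)
        g1 = _connected_gnp(n, p, rng)
        g2 = nx.relabel_nodes(_connected_gnp(n, p, rng), {i: i + n for i in range(n)})
        g = nx.union(g1, g2)
        bridge = 2 * n
        g.add_edge(bridge, int(rng.integers(n)))
        g.add_edge(bridge, int(n + rng.integers(n)))
        return g, PlantedTruth(bridge_nodes=(bridge,), **truth_kwargs)
    raise ValueError(f"unknown graph fixture kind {kind!r}")
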