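# Methods

This note documents the statistical procedures implemented in `dysbionet`,
the synthetic data model used to validate them, and the design decisions
taken where the methodology was genuinely open.

## Data model and conventions

The universal input is an integer OTU count matrix (samples × OTUs) with a
sample-metadata table assigning each sample to a group (NC, CCl4, MSC) and a
timepoint (48h, 1w, 2w); healthy controls exist only at 48 h, giving seven
cohorts (NC, C48, C1W, C2W, M48, M1W, M2W). Relative abundance (rows sum
to 1) is the substrate for distances, ratios and networks; the effect-size
screen uses parts-per-million (rows sum to 10⁶) so its scores land on the
familiar log₁₀ scale. Shannon diversity is reported in nats so that Pielou
evenness J = H/ln S is exact by construction; single-species samples get an
explicit *undefined* evenness rather than 0, to avoid biasing cohort means.
Rarefaction is not applied anywhere; diversity is computed on the counts as
given.

## Community comparison

**PERMANOVA.** One-way design on a Bray–Curtis distance matrix, using the
sums-of-squares identity SS_total = (1/n)Σ_{i<j} d²ᵢⱼ and
SS_within = Σ_g (1/n_g)Σ_{i<j∈g} d²ᵢⱼ, with
pseudo-F = (SS_between/(a−1))/(SS_within/(n−a)) and R² = SS_between/SS_total.
Sampled permutation p-values are +1-corrected,
p = (#{F_perm ≥ F_obs}+1)/(n_perm+1), which guarantees p > 0; in exhaustive
mode all distinct assignments of samples to groups of the observed sizes
(capped at 10⁵) are enumerated and the exact proportion is reported without
the correction. Only single-factor comparisons are supported, matching how
the statistic is used here. Under the null generator the test's type-I error
at α = 0.05 is 0.03–0.07 (verified over 1000 replicates in the acceptance
suite).

**SIMPER.** For two groups, each between-group sample pair (i, j)
contributes |y_ik − y_jk| / Σ_k(y_ik + y_jk) to OTU k; averaging over pairs
makes the contributions sum *exactly* to the mean between-group Bray–Curtis
dissimilarity (the conservation identity is asserted to 1e-10). The
conventional square-root transform of the unit-scale profile is applied
first by default; `transform="none"` is available because the choice of
pre-transform substrate is a judgement call.

**PAM and k selection.** Classic BUILD + SWAP k-medoids on the distance
matrix: BUILD seeds medoids greedily, SWAP applies the single best
strictly-improving exchange until convergence, so the objective descends
monotonically and the procedure is fully deterministic (ties break toward
the lowest index). Silhouettes are computed from the distance matrix,
s(i) = (b−a)/max(a,b), with members of singleton clusters (and the
all-identical degenerate case) assigned 0. `choose_k` returns the argmax of
the average silhouette (ties → smallest k) *and* the whole silhouette-vs-k
table, because real datasets can carry two near-optimal k values and the
secondary optimum is informative.

**Univariate tests.** Welch's t-test (safer than the pooled test under
unequal variances), standard one-way ANOVA, Bonferroni correction
min(1, m·p). Ratio-valued quantities (LIDR) are log₁₀-transformed before
testing by default; two all-constant equal groups give p = 1 by convention.

## Marker discovery (effect-size screen)

A reimplementation of the classic two-step recipe. Step 1: per-OTU
Kruskal–Wallis (tie-corrected, chi-square approximation) at α = 0.05; a
feature that is constant across all samples gets p = 1. Step 2: for features
passing the screen, 30 bootstrap rounds each draw two-thirds of every class
(a round is skipped if a class would fall below 3 samples), fit a two-class
Fisher discriminant with the within-class covariance regularized by εI,
ε = 10⁻⁶·trace/p (sparse OTU matrices are otherwise singular), and score
feature k as e_k = (|w_k|·d + |m̄₁ₖ−m̄₂ₖ|)/2 with w the unit-norm
discriminant and d the projected class-mean gap. The reported score is
log₁₀(1 + mean over rounds), thresholded at 2.0 by default. Designs with
more than two classes are handled one-vs-rest; an OTU is assigned to the
class with the largest one-vs-rest score among classes in which it is
actually enriched (class mean above rest mean), which keeps the per-class
marker sets disjoint. A subclass consistency step is not implemented — the
cohort design here is flat.

Two properties of this score are worth knowing. First, because the
discriminant weights are inverse-variance scaled, any feature with an
in-sample rank separation receives a non-trivial |w_k|, so the score of a
Kruskal–Wallis false positive is bounded below by roughly its abundance
scale; the 2.0 threshold therefore only filters features whose abundance is
below a few hundred ppm. Second, the chi-square approximation to the
Kruskal–Wallis null is accurate in the small-p tail where screening
decisions are made but can deviate from the exact permutation p by ~0.1 in
the mid-range at n = 8; the tests assert tail agreement and rank
concordance with a brute-force permutation oracle rather than uniform
closeness.

## Dysbiosis ratio (LIDR)

Marker sets are defined once, on the 48 h baseline: the screen above is run
on the injured (C48) versus healthy (NC) cohorts, giving a
disease-associated set D and a health-associated set H; both must be
non-empty or the ratio is undefined (an error, not a silent default). The
per-sample ratio LIDR = Σ_D p_k / Σ_H p_k is computed on relative
abundances, making it invariant to sequencing depth and to rescaling a
sample's counts, and exactly reciprocal under swapping D and H. A zero
denominator yields a flagged infinite score that is excluded from tests
with a warning; an optional pseudocount restores finiteness when wanted.
Within each arm, the three timepoints are compared by one-way ANOVA plus
Bonferroni-corrected pairwise Welch t-tests on log₁₀ ratios.

## Co-occurrence networks and gatekeepers

**Ensemble inference.** OTUs present in fewer than one third of samples are
dropped (rank-based measures are unstable on near-constant columns; the
threshold is exposed). Five measures are computed on relative abundances for
all remaining pairs: Pearson, Spearman, Bray–Curtis, symmetrized
Kullback–Leibler divergence (pseudocount 10⁻⁶, rows renormalized), and
mutual information on 4 equal-frequency rank bins, signed by the pair's
Spearman sign. Each measure proposes its top-1000 most-positive and
most-negative candidates (dissimilarities: smallest = co-presence, largest
= exclusion).

**ReBoot permutation null.** Each OTU column is permuted independently
across samples and every sample row is renormalized, so the null preserves
the compositional coupling induced by closure; correlations explainable by
renormalization alone are thereby discounted. Per-measure two-sided
p-values are centred on the null mean and +1-corrected.

**Merging and retention.** Per-measure p-values of a pair are merged with
Brown's method: the Fisher statistic −2Σln p is referred to a scaled
chi-square whose two moments are estimated empirically from the same
permutation draws (each null draw is converted to its within-null pseudo
p-value, so the dependence between measures is absorbed; with perfectly
duplicated measures the merged p equals the individual p). All measures
with a defined score contribute to the merge, not only the proposing ones.
Benjamini–Hochberg is applied across candidate edges; an edge is kept when
q ≤ 0.05 and at least two measures propose it with one consistent sign
(edges proposed with conflicting signs are discarded). Because permutation
p-values bottom out at 1/(n_perm+1), surviving a BH pass over ~5000
candidate pairs requires n_perm ≈ 1000; the default is set accordingly.
Hubs are ranked by degree with ties broken by OTU id.

**Fragmentation and the gatekeeper test.** F = 1 − Σ_c n_c(n_c−1)/(N(N−1)),
the fraction of node pairs with no connecting path (verified against an
exhaustive reachability oracle on small graphs). For a candidate node, the
observed statistic is F of the network with that node removed; the null
re-scores the *same* node's removal in 10,000 randomizations of the
network. "Identical node and edge distributions" is read as
degree-preserving randomization: double-edge swaps (≥ 10×|E| accepted swaps
per draw, attempt-capped so rigid graphs such as cliques simply return
unchanged) keep every node's degree and identity; the looser same-|V|,|E|
Erdős–Rényi null is available behind `null_model="gnm"`. The one-sided
p counts null fragmentation scores ≥ the observed one, +1-corrected; small
p means the node holds the real network together more than its degree
explains.

## Synthetic data model

Counts are drawn hierarchically per sample: a log-normal baseline
composition over OTUs (drawn once per study seed, σ = 1 by default);
cohort-specific multiplicative fold-changes on planted disease- and
health-associated OTU sets; a per-sample log-normal perturbation of every
OTU (σ = 0.5 by default) in which planted pairs are bivariate-normal with
the requested correlation (Gaussian copula); a Dirichlet draw around the
perturbed composition; and a multinomial read draw at fixed depth (row sums
equal the depth exactly). The Dirichlet concentration is parameterized *per
OTU* — the parameter vector is `concentration × n_otus × composition`, so
an average-abundance OTU has concentration ≈ 50 under the default — and
sample-to-sample overdispersion is dominated by the explicit log-normal
layer, which is what carries the planted correlation structure. A flat
total concentration of 50 spread over 150 OTUs would make per-OTU draws so
noisy that no planted correlation could survive into the counts.

The default study plants 15 disease and 15 health OTUs with fold schedule
C48 1.5×, C1W 3×, C2W 6× and M48 6×, M1W 1.5×, M2W 1× on the disease set
(health reciprocal), which reproduces the qualitative trajectory of
interest: the ratio of disease- to health-associated abundance starts high
under MSC treatment and falls toward the control level, while it rises
steadily in the untreated injured arm. The planted folds are test
conveniences, not effect-size estimates.

Two named benchmark fixtures freeze the validation conditions:

* `marker_benchmark_spec` — two cohorts of 10 at depth 5·10⁴ over 100 OTUs:
  20 planted 4-fold markers (10 up in each cohort, so the compositional
  mass shift cancels between classes) in the moderately-abundant range,
  75 background OTUs in the single-digit-count tail, and 5 dominant ballast
  taxa carrying most reads, with modest noise (log-sd 0.2, concentration
  1000). The rank-abundance shape matters: with a rare background, the
  Kruskal–Wallis screen is conservative (heavy ties) and the ppm-scale
  score threshold actually filters chance hits, giving sensitivity ≈ 1 and
  empirical FDR ≤ 0.1; with a flat, all-abundant community the score
  threshold cannot reject any screen-passing feature and the FDR floor is
  the raw α of the screen (~0.15).
* `correlation_benchmark_spec` — 30 samples over 100 OTUs at depth 10⁵ with
  20 disjoint planted ρ = 0.9 pairs carried by a unit-σ copula layer;
  planted pairs come out at empirical Spearman ≈ 0.8 and the ensemble
  network recovers ≥ 80% of them at ≤ 10% empirical FDR.

What the generator does *not* emulate: taxonomic correlation structure
(lineage strings are arbitrary), varying sequencing depth across samples,
batch effects, and zero-inflation beyond what the multinomial induces.
Passing the planted benchmarks therefore demonstrates correctness of the
inference machinery under the stated noise model, not performance on any
particular real dataset.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; the pipeline spawns
per-stage seeds from one master seed by hashing the stage name, and rerunning
a config reproduces byte-identical outputs (checksummed in the manifest).
The default gatekeeper null uses 10,000 randomizations; the pipeline's smoke
profile reduces permutation counts (networks 200, gatekeepers 1000) for
quick runs. The validation suite sizes its Monte-Carlo checks to what the
statistics need: 1000 replicates for test calibration, 100 seeds for
trajectory and clustering recovery, 50 replicates for marker recovery, 20
seeds for network recovery; `scripts/acceptance.py` uses somewhat smaller
replicate counts (50/20/5) to keep a full from-scratch rerun within a few
minutes on one CPU.

## Known limitations

* LIDR values depend on the recovered marker sets; with the weak baseline
  contrast of the default study (1.5× folds at C48), the derived sets are
  small (3–8 OTUs) and the absolute ratios are noisy, though the trajectory
  direction is stable.
* The effect-size score's discriminant term leaks global class separation
  into individual features (see above), so its threshold is a weak guard for
  abundant features; the Kruskal–Wallis α is the operative error control.
* Network inference at n = 6 samples per cohort (the real per-cohort size)
  has little power; per-cohort networks in the pipeline are frequently
  sparse or empty, which is reported as such rather than papered over.
* Bray–Curtis is a dissimilarity, not a metric; PERMANOVA and PAM never
  assume the triangle inequality, but ordination-style interpretations of
  the distances should keep this in mind.
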