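# dysbionet

Analytics for gut-microbiota recovery after chemically induced liver injury,
with and without mesenchymal-stem-cell (MSC) transplantation.

When mice receive a hepatotoxic CCl₄ challenge, their gut community shifts
away from the healthy state and then drifts back over days to weeks; MSC
transplantation changes the path of that recovery. `dysbionet` implements the
complete computational side of such a study for 16S OTU count tables:

* **Community comparison** — one-way PERMANOVA on Bray–Curtis distances
  (with an exact exhaustive mode for small designs), SIMPER decomposition of
  between-group dissimilarity into per-OTU contributions, and PAM
  (k-medoids) clustering with average-silhouette selection of k.
* **Marker discovery** — a self-contained effect-size screen in the LEfSe
  style: Kruskal–Wallis filter (α = 0.05) followed by a bootstrapped linear
  discriminant effect size on abundances scaled to 10⁶, reported as
  log₁₀ scores with the conventional threshold of 2.0.
* **Dysbiosis ratio (LIDR)** — the liver-injury dysbiosis ratio of a sample,

  ```
  LIDR = Σ_{k∈D} p_k / Σ_{k∈H} p_k
  ```

  where `D`/`H` are the OTU sets associated with the injured and healthy
  baseline cohorts at 48 h and `p_k` are relative abundances. The ratio is
  depth-invariant and is compared over time with log₁₀ t-tests / ANOVA with
  Bonferroni correction.
* **Co-occurrence networks** — CoNet-style ensemble inference over five
  association measures (Pearson, Spearman, Bray–Curtis, symmetrized
  Kullback–Leibler, rank-binned mutual information), ReBoot permutation
  nulls that discount purely compositional correlation, Brown's method to
  merge dependent per-measure p-values, and Benjamini–Hochberg control
  across edges.
* **Gatekeepers** — nodes whose removal fragments the network
  (F = 1 − Σ n_c(n_c−1)/(N(N−1))) more than in 10,000 degree-preserving
  rewirings of the same network.
* **Synthetic studies** — a Dirichlet-multinomial / logistic-normal
  generator that emulates the 7-cohort design (healthy control at 48 h;
  injured and MSC arms at 48 h / 1 w / 2 w, n = 6 each) with planted marker
  OTUs, planted pairwise correlations, and graph fixtures with known bridge
  nodes, so every stage can be validated against ground truth.

It is aimed at microbiome researchers who want a reproducible, scriptable
version of this analysis stack, and at methodologists who want the planted
benchmarks.

## Worked example

```python
import dysbionet as d

spec = d.default_study_spec(seed=11)          # 7 cohorts x 6 mice, 150 OTUs
table, metadata, truth = d.generate_study(spec)
by = {m.sample_id: m for m in metadata}

# largest community difference: the two arms at 48 h
pair = [s for s in table.sample_ids if by[s].cohort in ("M48", "C48")]
dm = d.distance_matrix(d.to_relative(table.subset_samples(pair)))
res = d.permanova(dm, [by[s].cohort for s in pair], n_perm=999, seed=0)
print(f"PERMANOVA M48 vs C48: R2={res.r2:.2f}, p={res.p:.3f}")

# dysbiosis-ratio trajectory with baseline-derived marker sets
disease, health, _ = d.define_marker_sets(table, metadata, seed=0)
scores = d.lidr_table(table, disease, health)
scores["cohort"] = [by[s].cohort for s in scores.index]
print(d.cohort_summary(
    {c: g.lidr.to_numpy() for c, g in scores.groupby("cohort")}))
```

prints

```
PERMANOVA M48 vs C48: R2=0.34, p=0.002
cohort  n  mean_lidr    se
   C1W  6      33.69  5.30
   C2W  6     152.81 34.90
   C48  6      15.03  1.54
   M1W  6      10.44  1.67
   M2W  6       3.76  0.89
   M48  6     242.11 89.12
    NC  6       3.93  0.59
```

The two arms are clearly separated at 48 h (R² = 0.34). The MSC arm starts
highly dysbiotic (mean LIDR 242 at 48 h) and falls toward the healthy-control
level (3.9) by two weeks, while the injured arm rises from 15 to 153 over the
same period — the planted recovery-versus-deterioration pattern, recovered
from counts alone.

The same pipeline runs from the shell:

```sh
dysbionet all --smoke --out-dir run1 --seed 1   # simulate + every stage
dysbionet simulate --out-dir data --seed 7      # just write otu_table.tsv etc.
dysbionet lidr data/otu_table.tsv data/metadata.tsv
```

## Layout

| Module | Contents |
| --- | --- |
| `dysbionet.core` | OTU table / metadata containers, TSV I/O, transforms, alpha diversity, Bray–Curtis |
| `dysbionet.simulate` | synthetic study generator, benchmark specs, graph fixtures |
| `dysbionet.compare` | PERMANOVA, SIMPER, PAM + silhouette, t-test/ANOVA/Bonferroni |
| `dysbionet.lefse` | Kruskal–Wallis + bootstrapped LDA effect sizes |
| `dysbionet.dysbiosis` | marker-set definition, LIDR, longitudinal contrasts |
| `dysbionet.network` | ensemble co-occurrence networks, hubs, fragmentation, gatekeepers |
| `dysbionet.pipeline` / `dysbionet.cli` | end-to-end orchestration, manifest, `dysbionet` command |

See `docs/methods.md` for the statistical details and design decisions.
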