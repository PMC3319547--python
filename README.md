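# proxistate

Tools for asking a deceptively simple question about nuclear
architecture: **do genome regions that sit close together in the nucleus
share an epigenetic state?**  The package takes interchromosomal Hi-C
contact counts at 1-Mb resolution, turns them into a spatial proximity
measure, and relates that proximity to the similarity of chromatin marks,
chromatin-state annotations, gene function, co-expression and
chimeric-RNA production between fragment pairs — with the permutation
controls, clustering and regression protocols needed to make those
relationships defensible.

It is written for computational genomicists who want the full analysis
chain as a tested, reusable library (plus a thin `proxistate` CLI), and
it ships a synthetic-data generator that plants known structure so every
stage can be validated end to end without any external download.

## The statistics at the core

* **Proximity.**  Raw interchromosomal contact counts `O(i,j)` are
  normalized to enrichment `C*(i,j) = O(i,j) / (f_i f_j T)` (observed
  over a coverage-product expectation, with `f_i` the fraction of read
  pairs containing fragment *i* and `T` the total count), then to the
  correlation matrix `C(i,j) = corr(C*_i, C*_j)` over shared usable
  entries.  `c(i,j) = C(i,j)` is the spatial proximity used everywhere.
  Only pairs on *different* chromosomes are analyzed, which removes
  linear genomic distance as a confounder.
* **Per-fragment signal.**  For a peak track, `S_f = Σ_p h_p · w_p`
  where `w_p` is the fraction of fragment *f* covered by peak *p*.
  Pairs are compared by the difference `D = |ln(1+S_i) − ln(1+S_j)|`
  and the average `A = (ln(1+S_i) + ln(1+S_j))/2`.
* **Chromatin states.**  Each fragment gets a composition vector `v`
  (`v_k` = fraction annotated as state *k*); two fragments are compared
  with the generalized Jaccard coefficient `Σ min(v_k,u_k) / Σ max(v_k,u_k)`.
* **Gene function and co-expression.**  GO term similarity uses Wang's
  graph-based semantic similarity (relation-weighted ancestor S-values),
  averaged over the m×n term-pair matrix of two fragments; co-expression
  is `E(i,j) = Σ_k g1_k g2_k r_k / (N_i N_j)` over database links
  spanning the pair.
* **Association.**  Proximity values are cut into 29 equal-width
  intervals, the 18 central intervals are kept (the extremes are sparse
  and the high tail is vulnerable to homology artifacts — a sequence-
  identity QC with a 92% identity cutoff, equivalent to a 75-nt read
  with 6 mismatches, profiles and flags them), and each feature is
  summarized by its per-interval median; Spearman's ρ between interval
  midpoints and medians is the headline statistic.
* **Controls, clustering, regression, chimeras.**  Gene payloads can be
  shuffled within chromatin compartments (gene positions and gene
  content intact); fragments are Ward-clustered by their proximity
  profiles; ridge regression predicts `c(i,j)` from the 24 D/A features
  under a fragment-level 2-fold × 100-split protocol with successive
  and greedy feature selection; cross-chromosome read pairs are profiled
  as the fraction of fragment pairs with a chimera per proximity
  interval, against a read re-pairing null.

## Worked example

```python
import proxistate as px

bundle = px.simulate(px.default_config(), seed=1)
table = px.build_pair_table(
    bundle.proximity, tracks=bundle.tracks, states=bundle.states,
    n_states=bundle.config.n_states, genes=bundle.genes,
    go_graphs=bundle.go_graphs, links=bundle.links)
bins = px.make_proximity_bins(table["proximity"].to_numpy())
for feat in ("D_expression", "A_DNAse", "jaccard", "go_CC"):
    prof = px.interval_profile(table, feat, bins)
    print(f"{feat:12s} rho = {prof.rho_medians:+.2f}  (p = {prof.p_medians:.2g})")

model = px.ProximityRegression.from_pair_table(table, alpha_policy=1.0)
results = model.fit(n_splits=20, seed=0)
print(results.summary())
```

prints

```
D_expression rho = -0.90  (p = 2.9e-07)
A_DNAse      rho = +0.80  (p = 7.9e-05)
jaccard      rho = +0.92  (p = 4.8e-08)
go_CC        rho = +0.99  (p = 1.1e-15)

Proximity ridge regression
============================================================
pairs: 6000   features: 24   alpha: 1
test RMSE (mean +- SD over 40 split evaluations): 0.4090 +- 0.0217
baseline RMSE (train-mean predictor): 0.4525 +- 0.0246
paired t-test p-value: 1.53e-12
```

Reading this: expression *differences* shrink as spatial proximity grows
(ρ = −0.90 over interval medians), while DNAse-sensitivity *levels*,
chromatin-state similarity and GO similarity all rise with proximity —
spatially close interchromosomal fragments look epigenetically alike and
functionally related.  The ridge model predicts proximity from the 24
pairwise signal features clearly better than the train-mean baseline
(test RMSE 0.409 vs 0.453, paired t-test p ≈ 1.5e−12).

The same stages are available from the shell:

```bash
proxistate simulate --seed 1 --out sim/
proxistate hic normalize --counts sim/counts.tsv --chrom-sizes chrom.sizes
proxistate associate --pairs pair_table.tsv --feature D_expression
proxistate run --config run.yaml --seed 1 --out run/
```

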