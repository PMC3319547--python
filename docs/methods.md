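# Methods

This note documents the models implemented in `proxistate`, the choices
made where the conventions in the field are ambiguous, the synthetic study
conditions the package validates itself against, and what passing those
validations does and does not demonstrate.

## Proximity from contact counts

The unit of analysis is a 1-Mb genome bin ("fragment"); chromosome-tail
bins shorter than 1 Mb are retained and weighted by their true length.
Coordinates are 0-based half-open throughout.

Raw Hi-C counts `O(i,j)` (symmetric, nonnegative) are reduced to the
interchromosomal set: only pairs of fragments on different chromosomes
enter any analysis, which removes linear genomic distance as a
confounder and sidesteps distance-decay normalization entirely.

Two normalization stages follow:

1. **Enrichment** `C*(i,j) = O(i,j) / (f_i f_j T)`, where
   `f_i = Σ_j O(i,j) / T` is the fraction of interchromosomal read
   pairs containing fragment `i` and `T` the total interchromosomal
   count.  `Σ_i f_i = 2` exactly (each pair is counted from both ends).
   A consequence worth knowing: because the coverage-product
   "expectation" double-counts pair membership, the mean of `C*` over a
   structureless Poisson model is about `F / (2·deg)` (≈ 0.5 for many
   chromosomes, where `deg` is a fragment's interchromosomal partner
   count), not 1.  Only relative enrichment matters downstream, so this
   constant is harmless; the test suite asserts flatness of the null as
   absence of structure, not unit mean.  Entries with zero expected
   count are masked.  `C*` is invariant under uniform scaling of `O`.
2. **Correlation** `C(i,j)` = Pearson correlation between rows `i` and
   `j` of `C*`, computed over fragments `k` usable in both rows with
   `k ∉ {i,j}` (self-entries would inflate the correlation).  Pairs
   with fewer than 3 shared entries or zero variance are masked.
   `c(i,j) = C(i,j) ∈ [−1,1]` is the spatial proximity value used by
   every downstream stage.  Externally normalized matrices can be
   injected at this point (`stage="external"`) and skip both steps.

### Sequence-identity QC

Apparent proximity can be manufactured by mapping errors and template
switching between highly homologous regions.  For a fragment pair the
identity level is

    I(i,j) = (merged hit length on i + merged hit length on j)
             / (len_i + len_j)

over homology hits at ≥ 92% identity (the cutoff equals the percent
identity of a 75-nt alignment carrying 6 mismatches).  Two genuinely
open conventions are exposed as modes: hits are merged by interval union
before summing (default) or summed raw; the denominator is the pair sum
(default, keeps `I ∈ [0,1]`) or per-fragment averaged.  The QC profile
reports the per-interval distribution of `I` and flags intervals whose
median exceeds 3× the global median (or, when the global median is
zero, whose upper quartile is positive) — the rationale for excluding
the extreme high-proximity intervals.

## Interval binning

Proximity values are cut into 29 equal-width intervals spanning the
observed range (the construction of the original interval edges is not
recoverable; equal width over the range is the simplest reproducible
choice).  The 18 central intervals are kept by default: 5 dropped at
the low end and 6 at the high end, where occupancy is low and the
identity QC concentrates its flags.  Both counts and the kept range are
configurable.  A value equal to the global maximum belongs to the last
interval (right-closed last bin).

## Pairwise feature statistics

* **Signal strength** (per fragment): `S_f = Σ_p h_p · overlap(f,p)/len(f)`.
  Peaks crossing bin boundaries contribute to each overlapped bin
  proportionally.  Punctate and domain-type marks are treated
  identically; at 1-Mb resolution their fine structure is immaterial.
* **Difference / average** (per pair): `D = |ln(1+S_i) − ln(1+S_j)|`,
  `A = (ln(1+S_i) + ln(1+S_j))/2`.  Signals are nonnegative, so a
  pseudocount is required for the logarithm to be defined at zero;
  `log1p` is the minimal convention and the default.  An
  `|ln((S_i+ε)/(S_j+ε))|` mode exists (`log_mode="epsilon"`); at
  typical signal scales the two orderings agree closely.
* **Chromatin states**: composition vectors `v_k` = fraction of the
  fragment in state `k` (uncovered bases allowed, `Σ v_k ≤ 1`);
  generalized Jaccard `Σ min / Σ max`.  A pair of fully unannotated
  fragments is masked (no information), not scored 1.
* **GO similarity**: Wang's graph-based measure with contribution
  weights `is_a = 0.8`, `part_of = 0.6` (the convention of the standard
  implementation; configurable).  A fragment's term list carries one
  occurrence per gene-term annotation; duplicates are retained by
  default (a `deduplicate` switch exists) and the pair score is the
  mean of the m×n term-similarity matrix.  The three namespaces are
  kept as disjoint DAGs and analyzed separately.
* **Co-expression**: `E(i,j) = Σ_k g1_k g2_k r_k / (N_i N_j)` summed
  over links with one gene overlapping each locus (both orientations,
  making `E` symmetric); `g` is the fraction of the 1-Mb locus covered
  by the gene and `N` the locus gene count.  Normalizing by link count
  instead is available as a mode.  Gene-free loci are masked.
* **Gene density**: genes assigned by the start of the coding region;
  the pair value is the mean of the two counts.

## Association statistic

Each feature is summarized per kept interval by its median (with
quartiles and extremes for the whisker-box view), and Spearman's ρ is
computed two ways: mode (a), the headline, between interval midpoints
and interval medians — matching the per-interval box plots — and mode
(b) across all pairs, reported as a secondary output because the two
can differ substantially in magnitude.  Note that mode (a) is a rank
correlation over at most 18 points: its null standard deviation is
roughly `1/√17 ≈ 0.24`, so single-replicate values near ±0.3 are not
individually meaningful, and replicate means are the right summary for
null controls.  Significance threshold for reported p-values: 0.05.

## Controls

* **Compartment-constrained gene shuffle**: within each chromatin
  compartment, gene payloads (name, expression, GO lists — and thereby
  co-expression identity) are permuted across gene positions.  Gene
  coordinates, per-fragment gene content and per-compartment payload
  multisets are exactly preserved, so any surviving association is
  attributable to compartment membership or gene density rather than to
  a finer proximity-epigenome coupling.
* **Chimera re-pairing**: read pairs mapping to one chromosome are
  unpaired and the pooled reads randomly re-paired across chromosomes
  (largest-pool-first matching, which maximizes the number of matched
  reads; unmatched leftovers are dropped and counted).  Per-chromosome
  read-position multisets — local coverage — are untouched.

## Clustering

Fragments are clustered by Ward's minimum-variance method on the
Euclidean geometry of their proximity profiles (rows of `C`, masked
entries imputed with the row mean); treating `1 − C` directly as a
dissimilarity is available as a mode.  Trees are cut at k ∈ {4, 8, 16,
32, 64} by default.  Summaries per cluster: within-cluster proximity
(usable interchromosomal same-cluster pairs), within-vs-outside
proximity, per-property median signal levels and median within-cluster
differences, and linear proximity (1/distance-in-Mb on the same
chromosome, 0 across chromosomes).  For the spatial-vs-linear
comparison the *mean* linear proximity is used: cross-chromosome pairs
contribute exact zeros, so the median is degenerate for any
chromosome-mixing cluster.

## Regression protocol

Ridge regression predicts `c(i,j)` from up to 24 features (D and A for
12 properties).  The evaluation unit is a fragment-level split: the
fragment list is halved at random, a pair joins the training (testing)
set only when both members are in the training (testing) half — pairs
crossing the halves are discarded — and the halves are then exchanged,
so 100 splits yield exactly 200 test RMSE values per model.  The split
list is fixed across models, enabling paired comparisons: model vs
train-mean baseline by a paired two-tailed t-test, Bonferroni-corrected
across screened features.  Features are standardized on training
statistics only; the intercept is unpenalized.  The penalty is chosen
by an inner 5-fold cross-validated grid (10⁻³..10³) on the training
half for single evaluations; the selection loops default to a fixed
λ = 1 on standardized features, since the evaluation protocol does not
depend on a particular penalty and per-fit cross-validation inside the greedy ×
stability loops buys no ranking changes at these sample sizes.
Successive selection ranks single-feature models by inner two-fold
validation RMSE (10 repeats) and grows the model in that order; greedy
forward selection re-scores all candidates at each step; stability is
the per-feature frequency of being selected within the first L steps
across outer splits (stable ⇔ frequency ≥ 0.9).  Aggregation curves
order pairs by a feature, group them (50,000 pairs per group at full
scale; configurable) and average both coordinates per group.

## Synthetic study conditions

The generator plants known structure so recovery can be asserted.  The
default genome is 6 chromosomes × 20 Mb (120 fragments, 6,000
interchromosomal pairs) with alternating 5-bin compartment blocks —
large enough for stable interval occupancy, small enough that the whole
suite runs in minutes.  A latent activity `a_i ~ N(μ_comp, σ_comp)`
(A: 1.3 ± 0.25, B: 0.7 ± 0.55 — the open compartment more active and
more internally coherent) drives every readout: peak tracks with
`S_f ∝ exp(±0.9·(a_f − ā))` (positive for active marks, negative for
methylation and H3K27me3), expression built from gene bodies
(`expr ∝ exp(1.3·(a − ā))`, gene density 6/Mb in A vs 4/Mb in B),
activity-dependent chromatin-state composition, compartment-biased GO
term pools on generated single-rooted DAGs of depth ≥ 3, co-expression
links with `r ≈ 0.7 − 0.35·|Δa|`, and chimeric read pairs at rate
`∝ exp(2.5·c(i,j))` using the *generated* correlation matrix as the
intensity covariate.

Contact counts are Poisson with rate
`∝ u_i u_j · exp(0.1·1[same compartment] + 1.2·s_i s_j + 1.2·hub(i,j)
− 1.2·|a_i − a_j|)` at 10⁵ total reads, where `s = sigmoid(a − ā)` and
`hub` marks shared transcription-factory membership among open
fragments.  The co-activity and factory terms are deliberate extensions
of a plain similarity-kernel model: the correlation stage of the
pipeline is invariant to monotone transformations of shared profile
structure, so a kernel-only model yields a saturated two-block
checkerboard in which the most isolated (inactive) fragments always
form the most coherent rows — level effects then come out inverted and
the proximity distribution has no continuum.  Non-separable hub
structure among active fragments is what plants the expected
organization: proximity varies continuously, difference features
anti-correlate with proximity, active-mark averages and state/GO
similarity correlate positively, methylation negatively.

Because single configurations cannot plant mutually exclusive
structures simultaneously, the named configurations each carry one
planted behavior and validation runs against the matching one:

* `default_config()` — graded couplings as above; difference, average,
  Jaccard, GO, co-expression and chimera effects.
* `compartment_decoupled_config()` — identical payload distributions in
  both compartments (activity continuum only, checkerboard 0.25, no
  hubs, kernel 1.6); validates that the gene shuffle nulls a purely
  positional coupling.  Any compartment-payload gap would survive the
  shuffle *by construction* — the control is designed to preserve
  compartment structure — so its specificity must be measured where
  the truth is null.
* `exclusive_factory_config()` — one hub per active fragment (6 hubs,
  κ = 1.5); plants a hard compact/loose cluster dichotomy: compact
  clusters are the active hubs (higher expression/DNAse, lower
  methylation), loose clusters the closed bulk.
* `two_block_config()` — checkerboard only; exact two-block recovery
  (adjusted Rand index 1) for Ward at k = 2.

Everything is deterministic given a seed; ground truth (compartments,
activities, hub memberships implicit in the rates) ships with each
bundle.

**What the synthetic validation does not show.**  The generator mimics
the statistical skeleton of real data, not its content: no sequence, no
read-level errors, no replication structure, no distance-dependent
intra-chromosomal physics (irrelevant here by design), Poisson rather
than overdispersed counts, idealized peak shapes, and a toy GO
ontology.  Passing recovery tests demonstrates that the estimators and
protocols are implemented correctly and are sensitive at realistic
effect sizes — not that real chromatin obeys the planted model.

## Numerical notes and degenerate inputs

Masked cells propagate as NaN and are excluded per-statistic with
logged counts.  Pearson values are clipped to [−1, 1] against rounding.
Zero-variance profiles, gene-free loci, all-zero state-vector pairs,
single-chromosome genomes, empty compartments and empty intervals are
all defined error or masked paths with tests.  Ward merges are
tie-broken deterministically by scipy's ordering, making clustering
reproducible for a fixed input order.  Seeds: every stochastic
operation takes an explicit seed; derived seeds stay below 2³¹.

## Limitations

Interval-median Spearman over 18 points is a coarse statistic with high
replicate variance (null SD ≈ 0.24); conclusions should rest on
replicate means, as the validation suite does for null controls.  The
identity-level denominator and the exact original interval edges are
reconstructions.  The pipeline assumes a fixed fragment universe shared
by all inputs; liftover between assemblies is out of scope, as are peak
calling, bias-model renormalization of Hi-C, and eigenvector-based
compartment calling (compartment labels are consumed as input).
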