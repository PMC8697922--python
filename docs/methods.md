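# Methods

`cernet` implements a competing-endogenous-RNA (ceRNA) network analysis
for a two-condition, multi-layer RNA-seq design: large (GF_C) versus
small (GF_T) ovarian follicles profiled at the mRNA, lncRNA, miRNA and
circRNA levels, a handful of pooled sample groups per condition.  This
note records the models, the defaults and the reasoning behind the
choices that the method descriptions leave open.

## Normalization

Each layer carries the field's conventional per-million scale:

- **FPKM** for mRNA/lncRNA: `1e9 * count / (length_bp * total_fragments)`.
  The length is the supplied effective transcript length; no
  fragment-length correction is applied.
- **TPM** for miRNA clean tags: `1e6 * count / total_clean_tags`.  A
  compatibility flag (`literal_formula`) evaluates the variant that
  divides by `total * 1e6` instead; it is off by default because it
  contradicts the per-million semantics of the unit.
- **RPM** for circRNA: `1e6 * C / N` over back-spliced junction reads.
- **2^-ddCt** for RT-qPCR, with multiple housekeeping references (e.g.
  GAPDH and U6) averaged arithmetically — the combination rule is a
  package choice; replicate groups with Ct SD above 0.5 cycles are
  flagged.

Differential testing operates on raw counts (with TMM factors), not on
these normalized values; the normalized matrices feed reporting and the
correlation gates.

## Differential expression

The test is a conditional negative-binomial exact test in the style of
the classic two-group exact test for overdispersed counts:

- **TMM factors.** Scaling factors by trimmed mean of M-values (30%
  trim on M, 5% on A, inverse-variance weights) against the sample
  whose upper quartile is closest to the mean upper quartile, then
  normalized to geometric mean 1.
- **Dispersion.** NB parameterization `var = mu + phi*mu^2`, one phi
  per layer by default.  Per feature the method-of-moments statistic
  `u = (pooled within-condition variance - mean) / mean^2` estimates
  phi; the common value is the median of `u` across features corrected
  for the median bias of a chi-square-distributed sample variance at
  the design's residual degrees of freedom, floored at 0.  A median
  (not a mean) is essential: a few genuinely heterogeneous features
  would otherwise inflate the common value by an order of magnitude.
  Per-feature values are shrunk toward the common value with a fixed
  weight of 0.7 and are available via `use_per_feature_phi`; the
  default uses the common value because tagwise moments are far too
  noisy at 2-3 replicates per group.  Parameter recovery: Poisson data
  give phi <= 0.02 at 50 replicates; phi = 0.2 is recovered within
  ±0.05 at 500 features x 10 replicates.
- **Exact test.** Conditioning on the total `t = sum_a + sum_b` of a
  feature's two group sums, every split `(x, t-x)` is enumerated under
  equal means scaled by the effective-library ratio, and the two-sided
  p is the conditional probability of all splits no more likely than
  the observed one (observed included, so p > 0).  The sum of n
  replicates with per-replicate dispersion phi is NB with dispersion
  phi/n, which is what the caller passes per group; at phi = 0 the
  conditional law is exactly binomial.  On null NB data (2,000
  features, 3 vs 3, phi = 0.1) the rejection rate at p < 0.05 averages
  0.050 over 30 simulations.
- **Calling.** log2FC on TMM-normalized condition means with
  pseudocount 0.5 (group-exclusive features are flagged rather than
  given infinite fold changes).  mRNA/lncRNA: |log2FC| > 1 and
  BH FDR < 0.05; miRNA/circRNA: |log2FC| > 1 and p < 0.05.  Every
  inequality is strict.  BH step-up was chosen as the FDR procedure.

## circRNA candidate filtering

Seven conjunctive criteria on back-splice junction candidates: exactly
one breakpoint; anchor overlap <= 2 bp; edit distance <= 2 bp; more
than 2 unique junction reads; best anchor mapping margin > 35 on at
least one side; unique reads > int(n_samples/2) (integer floor,
applied in addition to the fixed >2 rule — with six samples the sample
rule subsumes the fixed one); genomic span < 100 kb.  Coordinates are
BED-style 0-based half-open, span = end - start.  Survivors are
quantified in RPM.

## Pairing and network assembly

- **Prediction intersection.** miRNA-mRNA candidates must appear in
  all three prediction sources (the three-way intersection is the
  design; fewer tables are an error).
- **Correlation gates.** Negative coexpression: Spearman SCC < -0.7
  with p < 0.05.  ceRNA-mRNA coexpression: Pearson PCC > 0.9 with
  p < 0.05.  For n <= 8 samples both p-values come from full
  permutation enumeration (n! orderings); the t approximation with
  n - 2 df takes over for larger n.  At n = 6 the exact Spearman p
  makes the effective gate |SCC| >= 0.886 (p = 24/720 ≈ 0.033), which
  is what a strict p < 0.05 demands at that sample size.
- **Correlation scale.** All correlations are computed on
  log2(normalized value + 1).  Ranks — hence SCC — are unchanged by
  the monotone transform; for PCC the log scale measures proportional
  co-variation.  On the raw scale the single most abundant sample
  dominates the product-moment sum, and essentially any two strongly
  DE features appear "coexpressed" regardless of their per-sample
  profiles.  Configurable via `log_transform_correlations`.
- **Triplet admission.** For every gated (ceRNA, miRNA) and
  (mRNA, miRNA) pair sharing the miRNA, the triplet is admitted iff
  PCC(ceRNA, mRNA) > 0.9 with p < 0.05, evaluated with the exact
  permutation p at n <= 8.  The adaptive permutation null matters
  here: vectors that separate into two condition clusters keep a high
  r under all within-cluster permutations, so their permutation p
  cannot reach 0.05 and condition-driven pseudo-coexpression is
  rejected, while genuinely profile-coupled pairs reach p = 2/n!.
- **Network.** Nodes are DE RNAs only, typed and tagged with their
  regulation direction; edges are only the miRNA-incident pairs
  (circRNA-miRNA, lncRNA-miRNA, mRNA-miRNA); the ceRNA-mRNA
  correlation is a triplet attribute, not an edge.  Hubs are top-k by
  degree with deterministic lexicographic tie-breaking.  Export to
  GraphML (attributes preserved) and SIF (edge type as interaction).

## Enrichment

One-sided hypergeometric upper tail P(X >= k) per GMT term against a
user-supplied population (default: all quantified features of the
layer), BH correction across terms, significant iff corrected
p < 0.05 (strict).  No GO DAG propagation.

## Synthetic data

The generator emulates the study design, not its sequences: no reads,
no alignments.

- **Counts.** Baseline log2 means uniform on [3, 9]; NB counts with a
  single dispersion (default 0.02 — the libraries emulated are pooled
  follicle groups, whose biological heterogeneity is modelled
  explicitly by the latent profile terms below rather than folded into
  the count dispersion).
- **Planted DE.** Per-layer planted fractions default to the
  prevalence a whole-transcriptome follicle comparison reports
  (mRNA 0.5%, lncRNA 0.8%, miRNA 4.5%, circRNA 2.1%), effect
  |log2FC| = 2.  DE features also receive a within-condition latent
  profile (sd 3.0 in log2), block-normalized so the *arithmetic*
  condition means carry the planted fold change exactly.
- **Planted triplets.** Each triplet draws a per-sample latent
  z = ±delta/2 + b (delta = 3.5 by default) and sets
  miRNA = base + z, mRNA = base' - z + noise, sponge = base'' - z +
  noise, with noise sd `corr_noise_sd`.  The negated-identity link is
  monotone, so the latent miRNA-target SCC is exactly -1 and the
  latent sponge-mRNA PCC exactly +1 at zero noise.  The profile b
  shares one offset multiset between condition blocks (block T is a
  permutation of block C's draws), which makes the planted fold
  change exact for the miRNA and its mirrored targets alike, and is
  rejection-sampled for a minimum adjacent-rank gap (0.9·3/m log2
  units for m samples per condition) so count noise rarely permutes
  ranks.  Features whose latent means exceed 2^16 are shifted down as
  a whole (a per-feature constant preserves fold change, ranks and
  correlations; clipping would not).
- **circRNA candidates.** Fourteen deterministic boundary fixtures
  (one pass and one single-field violation per criterion) followed by
  random records; per-criterion truth verdicts are computed at
  generation time by plain predicate expressions.
- **Prediction tables.** True miRNA-mRNA pairs enter each of the three
  tables independently with probability `pred_sensitivity`; decoy
  pairs with `1 - pred_specificity`.
- **Streams.** One root seed, one spawn-key substream per output;
  equal configs are bit-identical, and adding an output never
  perturbs existing ones.

What the generator does *not* emulate: sequence content, mapping
artifacts, GC/length biases, correlated library-preparation effects,
or annotation errors.  Passing the recovery benchmarks therefore shows
the inference machinery is correct and calibrated under its own model,
not that real follicle data meet the model's assumptions.

## Benchmark problem sizes

The default layers are 2,000 mRNAs, 500 lncRNAs, 300 miRNAs and 1,000
circRNAs — a deliberate scale-down (the study quantified ~25,800 /
4,100 / 1,100 / 13,600) chosen so the full pipeline runs in seconds
while keeping every stage's statistics meaningful.  The
planted-triplet recovery benchmark runs 10 triplets at 5 samples per
condition over 20 seeds; 5 per condition is the sample size at which
the exact-permutation p-gates stop being the binding constraint.  At
the study's own 3+3 design the smallest achievable two-sided exact p
is 2/720, so with hundreds of candidate cross-pairs roughly 2% pass
any p < 0.05 gate by chance and precision among 10 planted triplets
saturates near 0.8 — an intrinsic property of six-sample designs worth
keeping in mind when reading the original network's edge list.

## Numerical choices

- Exact-test probabilities are computed in log space, shifted by the
  maximum and normalized over all splits; ties with the observed
  split's probability are included with a 1e-12 relative tolerance.
- The group-exchange symmetry of the exact test is exact in floating
  point (the two effective sizes enter symmetrically and the
  computation canonicalizes orientation before any division).
- Permutation p-values use a fixed permutation table per n (n <= 8),
  with a 1e-12 tolerance on coefficient comparisons.
- Degenerate inputs are errors, not silent NaNs: constant vectors for
  correlations, all-zero samples for TMM, zero totals for per-million
  scales; features with zero counts in both conditions are flagged
  `filtered` with an undefined p.

## Known limitations

- The exact test uses a plug-in conditional mean; for NB (unlike
  Poisson) the conditional law depends weakly on the unknown mean, so
  the test is exact only as the plug-in converges.  Calibration was
  verified empirically (above).
- Dispersion shrinkage uses a fixed weight rather than empirical
  Bayes.
- The hypergeometric enrichment treats terms independently (no DAG).
- With six samples, correlation gates at p < 0.05 are close to the
  information-theoretic floor of the design; network edges from such
  designs should be treated as candidates, not conclusions.
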