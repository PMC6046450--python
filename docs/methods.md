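# Methods

## Data model and filtering cascade

The unit of observation is an OTU × sample count table with one role
per sample (`biological`, `blank`, `negative_control`,
`positive_control`) and a metadata table describing the cross-foster
design (bird, origin nest, rearing nest, age class D8/D15, nest
treatment, morphometrics, PCR replicate).  The cascade order is fixed:

1. **Replicate merging.** Each biological sample's duplicate PCR
   replicates are averaged OTU-wise; fractional counts are retained
   until rarefaction.  Controls are never merged.
2. **Blank (mistag) subtraction.** For every OTU detected in at least
   one blank tag combination, its mean abundance over blanks is
   subtracted from that OTU in all other samples.  Results are floored
   at zero — a negative read count has no meaning — and blank columns
   are then dropped.
3. **Contaminant removal.** An OTU is a reagent/laboratory contaminant
   when its maximum *and* mean abundance are both strictly higher in
   negative controls than in biological samples (means over all samples
   of the role, zeros included).  Ties are retained as non-contaminants:
   removal is deliberately conservative.
4. **Abundance filtering.** After the controls are dropped, singleton
   OTUs (total ≤ 1) and OTUs whose dataset-wide total is strictly below
   0.005% of the grand total are removed.  The cutoff is evaluated on
   the table as it stands at this point (post-subtraction,
   post-decontamination), i.e. last in the cascade before rarefaction.
5. **Rarefaction.** Counts are rounded half-to-even, then each sample is
   subsampled without replacement (multivariate hypergeometric) to
   1,000 reads.  Samples below the depth are dropped and listed in the
   audit.  One generator seeded from `FilterParams.seed` is consumed in
   column order, so runs are bit-reproducible.

Every stage writes an audit entry whose read accounting balances
exactly (`reads_in = reads_out + reads_removed`).

## Diversity

Richness is the number of OTUs with count > 0 (no minimum-count
presence rule after rarefaction).  Shannon diversity is computed in
nats; evenness is Pielou's J' = H'/ln S, undefined (NaN) for S ≤ 1.
Beta diversity is presence–absence Jaccard; the distance between two
empty samples is defined as 0 to keep matrices total.  Temporal OTU
retention is |present(D8) ∩ present(D15)| / |present(D8)|, computed on
the rarefied table so both ages are compared at equal depth.

## Permutation statistics

**Mantel.** Statistic: Pearson correlation of the strictly-lower
triangles.  Null: simultaneous row/column permutation of the second
matrix.  One-tailed (positive association), matching how the test is
used here.  All permutation p-values carry the +1 correction and an
analytic-tie tolerance (a permuted statistic within 1e-10 of the
observed one counts as ≥), so enumeration ties are not lost to
floating-point noise.

**PERMANOVA.** The squared distance matrix is Gower-centred to G; for a
design matrix X with hat matrix H, the explained sum of squares is
tr(HG).  In margin mode each term's SS is the drop from the full model
to the model without that term, so every term is adjusted for all
others; with one term this reduces to the classical partition and, on
Euclidean distances of univariate data, the pseudo-F equals the
one-way ANOVA F to machine precision.  P-values come from free
permutation of sample labels (rows/columns of G).  Perfectly separated
designs produce an epsilon-negative residual SS, which is clipped to
zero and mapped to an infinite F so complement-labelling ties count
correctly.  Degrees of freedom are ranks of the design blocks (a
k-level factor spends k − 1 df); singleton factor levels and aliased
terms are rejected.

**PCoA and dispersion.** Eigendecomposition of G keeps
negative-eigenvalue axes (routine for Jaccard) as imaginary
coordinates rather than discarding them or adding Lingoes/Cailliez
constants, because the dispersion distances need them: the squared
distance of a sample to its group centroid is the real-axis squared
distance minus the imaginary-axis squared distance (Anderson's
correction), floored at zero before the square root.  Homogeneity of
dispersion is a one-way F on the centroid distances; the null follows
Freedman–Lane — residuals from the grand-mean model are permuted,
which for F is identical to permuting the distances themselves.
Singleton groups get distance 0 and are excluded from the F test.

**Feature tests and allometry.** Welch's unequal-variance t with
Welch–Satterthwaite df and Benjamini–Hochberg q-values over all tested
features; features with zero variance and equal means in both groups
are reported as t = 0, p = 1.  The SMA (type-2) slope is
sign(r)·sd(y)/sd(x) — appropriate when both axes carry error, as
log-tarsus and log-mass both do.

## Mixed models

Responses with repeated measures (two ages per bird, birds nested in
shared nests) are fit as Gaussian linear mixed models with random
intercepts, estimated by REML (statsmodels MixedLM).  Crossed random
factors (bird and nest) are encoded as variance components on a single
enclosing group.  Optimizers disagree near the variance boundary —
lbfgs can report convergence on a degenerate fit — so the fitter runs
lbfgs, Powell and CG and keeps the best-likelihood converged result.
Backward elimination, where requested, drops one fixed term per step by
largest Wald p ≥ 0.05; random effects are never eliminated.  The
sibling contrast reports both a two-sided Wald p and a one-sided
`p_convergence` for the directional hypothesis that shared rearing
draws communities together (foster pairs closer than separated true
siblings); the direction matters because shared origin alone already
makes separated true siblings more similar than strangers.

## The synthetic-study generator

`SimParams` defaults are the study conditions: 26 nests × 6 nestlings
(9 cross-fostered pairs exchanging 3 nestlings each, 8 control nests),
two ages, duplicate replicates at ~10,000 reads, 600 community OTUs
plus 50 contaminants, 8 blanks and 4 negative controls.

* **Communities.** OTUs are partitioned into phyla; per-nest D8
  profiles are Dirichlet draws around a phylum-weighted lognormal pool
  (concentration 20), birds are Dirichlet draws around their nest
  (concentration 300), and counts are multinomial — the standard
  Dirichlet-multinomial overdispersion model for OTU tables.
* **The age shift.** Each nest has a D15 environment: a mixture of the
  nest site profile (weight 0.6) and the mean D8 profile of its current
  occupants.  The environment is phylum-reweighted (Firmicutes × 2.0,
  Proteobacteria × 0.35) and its rare tail geometrically down-weighted.
  A bird's D15 profile mixes this target (weight λ = `convergence`,
  default 0.85) with its own D8 profile, then applies a per-bird tail
  down-weight `diversity_drop × (1.5 − u)` where u ~ Beta(2,2) is the
  bird's latent diversity-retention quality.  Tail down-weighting
  scales OTU i by (1 − drop)^(3·rank/exp(H')) — ranks relative to the
  profile's effective richness — so detected richness falls
  continuously without deleting OTUs.  `nest_concentration = 20` and
  `diversity_drop = 0.4` were chosen so rarefied richness falls in the
  ~50 → ~36 range typical of nestling cloacal communities at these
  ages; they are documented as tunable.
* **Controls.** Contaminants follow a shared lognormal reagent profile:
  abundant in negative controls (multinomial at depth 1,500–3,000),
  trace Poisson reads in biological samples, absent from blanks.
  Blanks receive Poisson(`blank_rate`) mistag reads drawn from the
  pooled biological profile.
* **Morphometrics.** A latent log body size drives both tarsus
  (mean 19.3 mm) and mass (log-log slope 1.87, D15 mean 18 g); tarsus
  and mass carry separate measurement/residual noise (sd 0.008 and
  0.012 on the log scale), because SMA is the right estimator exactly
  when both axes have error.  Weight gain couples to the retention
  quality u through `condition_coupling` on log D15 mass; a
  configurable fraction of birds (default 2.5%) is forced to
  non-positive gain to exercise the exclusion rule.

All randomness flows from one seed through a single generator in a
documented order (community structure → counts in sample order →
controls → morphometrics).

**What the generator does not emulate:** phylogenetic structure among
OTUs, sequence-level artefacts (chimeras, quality), nest-level
covariates (brood size, hatch date), seasonal or spatial effects, and
the much weaker signal-to-noise of field data — synthetic Mantel
correlations (~0.65–0.97) are far higher than field values.  Passing
recovery tests therefore demonstrates correctness of the machinery
under the assumed statistical structure, not field-data effect sizes.

## Problem sizes and determinism

Calibration tests use 500 replicates of small instances (n = 12–20
samples, 99 permutations); enumeration oracles use ≤ 6 samples where
the full permutation group is tractable; design-recovery tests use 20
replicate studies at full design size with 49–199 permutations where
only the statistic, not a fine-grained p, is needed.  Production
analyses default to 1,000 permutations.  Every stochastic component
takes an explicit integer seed; identical configs reproduce
byte-identical outputs.

## Known limitations

* PERMANOVA uses free permutation; the repeated-measures structure is
  handled by running ages separately, not by restricted permutation.
* Reported factor df are levels − 1; analyses that collapse a factor to
  a single-df contrast will print different subscripts for the same F.
* The dispersion F-test floors imaginary-corrected squared distances at
  zero; with very strong negative eigenvalue mass this slightly biases
  distances upward.
* `MixedLM` Wald p-values are asymptotic (no Kenward–Roger/Satterthwaite
  small-sample correction).
* Backward elimination tests terms one at a time; heavily collinear
  fixed effects can be eliminated in an order-dependent way.
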