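# Methods

## Data model and preprocessing

A `FeatureTable` holds integer counts (features × samples), per-sample
metadata and per-feature 7-rank lineages. The sentinel value `Unknown`
marks missing metadata and is excluded per factor before any statistic —
it is never treated as a category. Preprocessing operations and their
conventions:

* **Depth filter** keeps samples with total count *strictly greater than*
  the threshold (default 1000 reads); the post-tree-merge filter in the
  cophylogeny scan keeps samples retaining *at least* 10 reads. The
  asymmetry follows the wording of the protocols these steps mirror; both
  thresholds are configurable.
* **Rarefaction** subsamples each sample to exactly the target depth
  (default 1000) without replacement via multivariate hypergeometric
  draws; samples below the depth are dropped. Deterministic given a seed.
* **Taxonomy collapse** sums features sharing a lineage prefix; features
  unannotated at the target rank pool under
  `unclassified <deepest annotated ancestor>`, conserving the grand total.
* **Rare-feature purge** drops features whose total is below a relative
  cut (default 1e-4 of the grand total, inclusive at the boundary);
  idempotent.
* **Mitotype assignment** dereplicates exact sequence variants
  (case-insensitive), filters them at a total count of at least 100, flags
  host (mitochondrial) variants with a caller-supplied classifier, and
  assigns each sample the most abundant host variant. Ties break to the
  lexicographically smallest variant id — an arbitrary but deterministic
  rule.

## Diversity

Alpha: observed features; Pielou's J = Shannon H (base e over observed
features) / ln S, undefined (NaN) for single-feature samples; Faith's PD
as the branch length of the minimal rooted subtree spanning the present
tips (root inclusive). Beta: Bray-Curtis, binary Jaccard, unweighted
UniFrac, and weighted UniFrac in its **raw** (non-normalized) form by
default, with the normalized variant behind a flag — both variants are in
circulation and the choice matters for absolute values, not for the
permutation tests built on them. Features absent from the microbial tree
are dropped from tree-based metrics with a warning, mirroring the
upstream alignment-failure pruning such tables have usually received.
Matrix computation is delegated to scikit-bio/scipy; the package's own
pairwise implementations exist as the reference definitions and are tested
against hand-computed values.

## Phylosymbiosis statistics

All permutation p-values use (count + 1)/(n_perm + 1); under exact
enumeration the identity permutation plays the role of the +1. Defaults:
999 permutations.

* **Mantel**: Pearson correlation of the off-diagonal entries, one-sided
  (positive association) by default — the phylosymbiosis hypothesis is
  directional — with a two-sided alternative by flag.
* **Distance classes**: Sturges' rule guides the class count — about
  1 + log2 of the number of *pairs* for Mantel correlograms (11 classes
  for ~500 pairs) and of the number of *tips* for univariate trait
  correlograms (6 classes for 32 tips). When a host tree contains a few
  discrete deep divergences, each distinct distance above a threshold
  becomes its own singleton class and the remaining range is split into
  equal-width classes. Manual breaks are honored verbatim as half-open
  intervals.
* **Mantel correlogram**: per class, the Mantel correlation between the
  community dissimilarities and the class indicator matrix, sign-flipped
  so positive means within-class pairs are more similar than expected;
  two-sided permutation p per class with a progressive Holm correction in
  class order (class k adjusted within the first k raw p-values).
* **Moran's I correlogram**: per-tip traits (within-host replicates
  averaged first), I with the class indicator as weights, permutation null
  expectation −1/(n−1). The 95% CI is a recentred percentile interval:
  the spread of I under trait permutation shifted onto the observed value.
  This is one of several defensible constructions; it is declared here
  because the convention behind published correlogram CIs is rarely
  stated. A class is positive-significant when the CI lower bound exceeds
  −1/(n−1).
* **PERMANOVA**: single factor at a time, pseudo-F and R² from the
  Gower-centered inner-product matrix, free permutation of labels, 999
  permutations. Continuous covariates enter as a single-df regression.
  Adjusted R² = 1 − (1 − R²)(n − 1)/(n − df − 1) makes factors with
  different level counts comparable; Z-scoring adjusted R² within factors
  shows which compartment responds most to each factor; Bonferroni
  correction spans the full factor × compartment family.

## The cophylogenetic binary GLMM

For each prevalent microbial group (family presence in >50% of samples of
at least one compartment), occurrence y of variant m in sample s is

    y ~ Bernoulli(logit⁻¹(η)),
    η = β₀ + β₁·ln(depth_s) + Σ_k u_k[level_k(s,m)] + e_{s,m},

with nine structured random effects u_k ~ N(0, σ²_k V_k): host phylogeny
(V = Aₕ, the unit-diagonal Brownian covariance of the host tree), host
identity (I), microbe phylogeny (Aₘ), microbe identity (I), the four
host×microbe interactions with V = Aₕ⊗Aₘ (cophylogeny), Aₕ⊗I, I⊗Aₘ, I⊗I,
and area×microbe identity (I). Host and microbe covariances are
standardized to unit diagonal before the Kronecker products so ICCs are
comparable across terms; this also removes any dependence on overall tree
height. The observation-level Gaussian effect e has variance fixed at 1 —
the residual is not identifiable from binary data, and fixing it sets the
scale of all variance components.

**Sampler.** Pólya-Gamma augmentation (exact Devroye rejection sampler,
vectorized; validated against E[PG(1,z)] = tanh(z/2)/(2z)) makes every
conditional Gaussian. Random-effect blocks are drawn exactly via
u = Q⁻¹(b + Lz) with Q = diag(Z'ΩZ) + V⁻¹/σ² and L its Cholesky factor;
when one Kronecker factor is an identity the system splits into
independent small blocks solved batched. Variance components alternate,
iteration by iteration, between conjugate scaled-inverse-χ² draws and a
marginal Metropolis random-walk step on log σ² with the block integrated
out (step 1.0 on the log scale). The marginal step is essential: plain
conjugate Gibbs cannot traverse the low-variance funnel and produces
effective sample sizes an order of magnitude too small on null terms.

**Priors.** Scaled-inverse-χ² with df 0.002 and scale 1 per component
(fixed effects N(0, 100)). The near-flat df is deliberate: with df 1 the
prior puts a floor of roughly scale/df-many units of variance under every
low-dimension component, which inflates null ICC lower bounds above the
0.01 call threshold — the calibration suite demonstrates this directly.
Priors are configurable; the suite includes a prior-sensitivity check
showing significance calls are unchanged under halving/doubling of the
scale.

**Summaries.** ICC_k = σ²_k/(Σσ² + 1 + π²/3) per retained draw (the logit
link variance π²/3 is included in the denominator — a declared convention,
since published ICCs for binary models do not always state it); 95%
highest-posterior-density intervals by the exact shortest-window rule; ESS
by Geyer's initial-positive-sequence truncation. A term is significant
when its ICC lower bound strictly exceeds 0.01; any component with ESS at
or below 200 marks the whole fit not converged, and calls from
non-converged fits are masked.

**Chains.** Desk-scale defaults are 20,000 iterations, burn-in 5,000,
thinning 10 (tens of seconds per fit at 540 observations); analysis and
test drivers use 1,000–20,000 iterations depending on what they measure,
stated per driver. Production-scale settings (e.g. 1,250,000 / 250,000 /
50) are plain configuration.

## Community count GLMM

Genus counts follow a Poisson log-link model with the sample's log total
as offset; per-genus intercepts and covariate slopes; random effects for
sample (compositionality), area×genus, host-phylogeny×genus (Aₕ) and
host-identity×genus; and a per-genus residual variance. Latent log-means
get a vectorized Metropolis update (proposal scale 2.4/√(λ + 1/σ²_e));
everything else is conjugate. A genus-covariate effect is significant when
its 95% HPD excludes zero. Under all-null simulation this rule fires at
close to the nominal 5%.

## The synthetic-data generator

`simulate_tree` draws pure-birth (Yule) trees, scaled to unit height, so
covariances are already unit-diagonal up to standardization.
`simulate_cophylo_dataset` draws occurrence data from exactly the model
the GLMM fits — latent logits from the nine structured terms with chosen
variances — so true ICCs are known in closed form; a
truncated-negative-binomial count layer (dispersion 0.5, cell mean
depth/n_microbes) exists only so table operations can run on the output.
Sequencing depths are lognormal with median ≈14,000 reads and log-sd 0.5,
the scale of a typical MiSeq amplicon survey. The canonical validation
scenario is 12 hosts × 3 samples/host × 15 microbes with cophylogeny
variance 4 against 0.25 for every other term (true cophylogeny ICC 0.39),
plus an all-null variant. `simulate_phylosymbiosis_table` evolves feature
log-weights by Brownian motion on the host tree (σ 1 per unit height for
the strong-signal compartment analog) with iid logit noise and multinomial
sampling at fixed depth; `simulate_genus_table` adds known covariate
slopes for the community model.

What the generator does **not** emulate: sequencing error and chimeras,
taxonomic misannotation, compositional coupling between families, spatial
autocorrelation of areas, overdispersion structure of real amplicon
counts, and any relationship between depth and biology. Passing tests
therefore demonstrate that the estimators recover the structures they
model, under the model — not that real coral data meet those assumptions.

Emergent-pattern checks tie the generator to the statistics end to end:
Brownian tables yield significant Mantel tests and a positive-significant
first correlogram class in ≥90% of replicates; strong cophylogeny variance
makes host cophenetic distance predict between-host community Jaccard. For
that Jaccard check the host profile is majority-rule occurrence across 5
samples/host over 60 microbes: with fewer microbes or any-sample presence
the binary profiles saturate and the check measures noise rather than the
generator. That sizing was fixed by a power argument before the seeds were
frozen.

## Numerical conventions

Symmetry/PSD tolerance 1e-8 (relative); covariances get jitter
1e-8·trace/n before inversion and fail loudly if still not positive
definite. Zero-length branches are legal (covariance ties become exact).
Trees need not be ultrametric except for unit-depth scaling (tip-depth
spread ≤1e-6 relative). Permutation comparisons use a 1e-12 slack so ties
count as exceedances. Degenerate inputs are explicit: both-empty samples
give NaN distances; constant traits, zero-weight matrices and
single-level factors raise; a degenerate metric in the pipeline logs a
warning and records NaN instead of aborting the screen. All simulation
and inference functions take explicit seeds; pipeline runs derive
per-task seeds from the config seed and are byte-reproducible.

## Known limitations

* At the bundled simulation size the cophylogeny ICC posterior keeps some
  mass near zero even when the posterior mean sits at the simulated truth:
  540 binary observations cannot fully separate A⊗A from I⊗I covariance
  structure. The HPD-lower-bound flag is therefore conservative at desk
  scale — the validation suite checks the posterior-mean *ranking* of
  interaction terms (correct in ≥8/10 fits), and the analysis driver
  prints the ranking as the informative output. With survey-scale data
  and production chains the flag behaves as intended by construction.
* ESS of near-zero variance components is intrinsically poor in any Gibbs
  scheme of this family; the not-converged flag is doing its job when it
  fires on null-like fits.
* The Mantel correlogram's progressive Holm correction and the recentred
  percentile CI of the Moran correlogram are conventions, not uniquely
  correct choices; both are isolated behind parameters.
* Multi-factor (marginal) PERMANOVA, dispersion tests, model comparison
  (DIC/WAIC) and parameter-expanded priors are out of scope.
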