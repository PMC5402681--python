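# Methods

## Model and null fit

Traits follow a generalized linear model: for continuous Y, a linear
model with i.i.d. N(0, σ²) errors; for binary Y, a logistic model.  The
null hypothesis is that all OTU coefficients are zero, so the null model
contains only an intercept and the covariates.  Continuous nulls are fit
by ordinary least squares, binary nulls by logistic maximum likelihood
(statsmodels GLM).  The fit supplies the per-sample prediction μ̂₀, the
residuals r = Y − μ̂₀ and the dispersion Φ: the unbiased residual
variance RSS/(n − q − 1) for continuous traits and exactly 1 for binary
traits.  Because permutation inference is rank-based, the Φ divisor
convention cannot change any p-value; it only scales the reported Q.

Every statistic in the package is a function of r, so one null fit per
dataset serves every taxon and every candidate statistic.

## Compositions and scores

Counts are converted to per-sample proportions (rows sum to 1; samples
whose total is zero must be dropped during harmonization, and the
readers do that with a warning).  Each OTU column is standardized to
mean 0 and unit *sample* standard deviation (ddof = 1); the same ddof = 1
convention is used everywhere a standard deviation appears, including
the `scale` operator of the outcome simulator.  Constant columns are set
to zero and flagged rather than producing NaNs, so small-taxon tests
stay defined.  The per-OTU score is U_j = Σ_i r_i Z_ij; its sign ("+"
iff U_j ≥ 0) is the reported effect direction.

## Distances and kernels

Seven candidate measures: Bray-Curtis, unweighted UniFrac, weighted
UniFrac, generalized UniFrac with α ∈ {0, 0.25, 0.5, 0.75}.  UniFrac is
computed from branch profiles: for each tree edge, the per-sample sum of
proportions of the OTUs descending through it.  The leaf-to-edge
incidence is built once per (sub)tree and reused, so a permutation study
pays the traversal cost once.  Choices worth recording:

* Weighted UniFrac is the **normalized** variant (range [0, 1]).  The
  min-P combination compares p-values across measures, and a bounded
  distance keeps all seven kernels on a comparable scale; the raw
  variant is unbounded.
* A sample pair whose UniFrac denominator is zero (neither sample has
  any mass on the tree) gets distance 0 with a warning; this can only
  happen inside small-taxon subgroup scans.
* All node degrees are handled uniformly through edges; multifurcations
  need no special casing.
* Kernels are K = −½ J D² J (J the centering operator), verified
  entrywise against the explicit matrix product in the tests, followed
  by eigenvalue clipping at zero.  Bray-Curtis kernels are generally
  indefinite; clipping is the established repair and keeps Q ≥ 0.  The
  repair is flagged on the kernel object.
* Within a taxon subgroup, distance computations use the subgroup
  counts renormalized to per-sample subgroup proportions (samples with
  zero subgroup total keep an all-zero profile), while SPU always uses
  the full-community standardized columns of the member OTUs — the
  community-level percentages are the working scale of the score tests.

## Permutation inference

All tests share one `PermutationSet`: B seeded uniform permutations of
the sample indices applied to the residual vector.  Residuals (not
outcomes) are permuted for both trait types, consistent with the score
formulation in which covariate effects are absorbed into μ̂₀.  P-values
use the add-one estimator (1 + #{s^(b) ⪰ s_obs})/(B + 1), with ties
counted as exceedances (conservative) — so p ∈ [1/(B+1), 1] and an
exact zero is impossible.  Sign-bearing statistics (SPU for every γ,
aggregate, single-OTU) are compared by absolute value; the kernel
statistic Q is one-sided.  Even-γ SPU statistics are non-negative, so
the absolute-value convention is a no-op there.

Adaptive tests use a single-layer leave-one-out min-P construction on
the same set: each permutation's per-candidate pseudo p-value is its
exceedance count within the permuted sample (self included, playing the
add-one role) divided by B; the null min-p sample is the row-wise
minimum; the final p-value compares the observed minimum p against it.
With a single candidate this reduces exactly to the plain permutation
p-value, which the tests assert.  No nested resampling is needed, which
is what makes a full-rank scan computationally feasible.

Default B is 50,000 for a single analysis (CLI-overridable); the
simulation experiments use B = 1,000 per replicate and the fast scan
profile uses B = 5,000.

## The rank scan

Groups are formed per rank from the Greengenes-style lineages, keyed by
the full lineage prefix so same-named taxa under different parents stay
distinct.  OTUs unassigned at a rank are not formed into a pseudo-taxon
and are not tested at that rank; they remain members of their named
higher-rank taxa.  The kingdom rank always contains the entire-community
group (named kingdom groups are added only if more than one named
kingdom exists), so the community-level test is a first-class scan row.
Configuration per taxon: ≥2 OTUs with phylogenetic disparity → full
OMiAT (or the chosen engine); ≥2 OTUs but UniFrac uninformative (any
zero pairwise denominator or an all-zero UniFrac matrix) → SPU pool plus
the Bray-Curtis kernel only; exactly one OTU → two-sided score test.
Subtrees are pruned per taxon (degree-2 nodes collapsed with lengths
summed, preserving cophenetic distances).  Benjamini–Hochberg adjustment
runs within each rank; a taxon is discovered when q ≤ 0.05.  Because
every taxon shares the fit and the permutations, a re-run with the same
seed reproduces the scan byte for byte, and per-taxon p-values equal the
standalone tests run on the same permutation set.

## Synthetic data

The generator emulates a filtered infant-gut 16S profile:

| parameter | default | rationale |
|---|---|---|
| OTUs p | 71 | post-filter community size of the emulated profile |
| subjects n | 100 | simulation cohort size |
| library sizes | NB(mean 300, size 10), zeros redrawn | shallow, overdispersed sequencing depth |
| proportion means π | power law π_j ∝ 1/j | rank-abundance curve: top OTU ≈ 21%, rarest ≈ 0.3%, all above the 10⁻³ mean-proportion filter |
| overdispersion θ | 0.02 | typical stool-community Dirichlet-multinomial dispersion |
| tree | random binary joins, Exp(0.1) + 0.01 branch lengths | stand-in phylogeny; synthetic, not a real clade structure |
| clusters | PAM, k = 5, on cophenetic distances | phylogenetically coherent associated sets |

θ parameterization: Dirichlet concentration = π(1 − θ)/θ, so θ → 0 is
multinomial and the compositional variance inflation factor is
1 + (N − 1)θ.  The moment estimator (`estimate_dm_params`) is the
pooled-proportion π̂ with the weighted between/within mean-square
estimator for θ; a recovery test checks it at n = 500.

Outcomes: linear predictor 0.5·scale(X1 + X2) + Σ_{j∈Λ} β_j·scale(Z_ij)
with X1 ~ Bernoulli(0.5) and X2 either independent N(0, 1) or
OTU-correlated (Σ_{j∈Λ} scale(Z_ij) + N(0, 1)); continuous traits add
N(0, 1) noise, binary traits are Bernoulli(logit⁻¹).  Λ is chosen by
scenario: top/bottom 10% by mean proportion (round(0.1p), minimum 1), a
random 10%, or one PAM cluster drawn uniformly per replicate.  Effects
are U(0, c) (same direction) or U(−c, c) (mixed), c ∈ {1, 2, 3}.  Under
the type-I-error null all β are zero; when X2 is OTU-correlated the
associated set (a random 10% per replicate) still drives the covariate,
so the null genuinely exercises covariate adjustment.  Binary outcome
draws that produce a single class are redrawn.

PAM is the classic deterministic build + swap on the precomputed
cophenetic matrix with ties broken toward the lowest index, so cluster
assignments are a pure function of the tree.

What the generator does **not** emulate: real taxonomic structure (the
synthetic taxonomy nests genera inside PAM clusters), longitudinal
sampling, zero-inflation beyond what the Dirichlet-multinomial induces,
and real phylogenies.  Passing tests therefore demonstrate the
statistical properties of the methods under a realistic abundance and
dispersion regime, not agreement with any particular real cohort.

## Experiment scales

Problem sizes are chosen so the full validation runs comfortably on a
single CPU: the test suite checks type-I calibration at 400 replicates ×
400 permutations per cell (tolerance ±2 Monte-Carlo SE at that replicate
count), power orderings under the logistic model at 150 replicates × 500
permutations per cell, and planted-signal recovery at B = 5,000.  The
acceptance script runs the type-I study at 2,000 replicates × 1,000
permutations per cell.  The aggregate-test near-nominal check constructs
exactly balanced ± effect pairs, since that is the regime in which the
aggregate predictor cancels; under U(−c, c) draws the realized effect
sum is nonzero and the aggregate test retains some power.

## Known limitations

* Inference is permutation-only; no asymptotic (Davies/moment-matching)
  p-values are provided, so very small p-values are floored at
  1/(B + 1).
* No overdispersed-count or zero-inflated null models; the null is a
  standard GLM in the trait.
* No hierarchical gatekeeping across ranks — FDR is controlled within
  each rank separately.
* The Bray-Curtis-only fallback triggers whenever *any* UniFrac measure
  is uninformative (e.g. every OTU of the group present in every
  sample), which is deliberately conservative for small taxa.
* No rarefaction is applied; compositions are computed from the counts
  as given.
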