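# Methods

This note documents the models, estimators and numerical choices behind
`raresoil`, and what its synthetic-data suite does and does not establish.

## Study system and data model

The package analyses disturbance-recovery mesocosm experiments on soil
bacterial communities: two soil microbiotas conditioned by long-term
chemical (NCF) or organic (NOF) fertilization are exposed to drought (DR),
flooding (FL), freeze-thaw cycles (FR), heat (HE), or left ambient (AMB),
and profiled by 16S amplicon sequencing before disturbance (`initial`) and
at 0, 2, 40 and 170 days of recovery, with four replicates per cell.  The
in-memory unit is an integer OTU-by-sample count matrix with aligned sample
metadata; all analyses assume depth-equalized (rarefied) counts.

## Taxon categories

OTUs are classified per soil from that soil's initial samples only, using
two relative-abundance cutoffs, 0.01% (rarity) and 1% (abundance):
always/conditionally abundant (AAT, CAT), moderate (MT),
conditionally/always rare (CRT, ART), and conditionally rare-and-abundant
(CRAT).  Boundary convention: the rarity test is strict (`< 0.01%`; a value
exactly at 0.01% is moderate-side) and the abundance test is inclusive
(`>= 1%`).  OTUs absent from every initial sample of a soil are `NEW`; they
are grouped with the rare taxa, as are CRAT OTUs by default (configurable —
CRAT is a logical possibility the two-cutoff scheme admits but that rarely
occurs in practice).  The two-way grouping used everywhere downstream is
abundant = AAT+CAT, common = MT, rare = ART+CRT+NEW.

## Diversity and community structure

Shannon diversity H = −Σ p_i ln p_i (natural log) is computed per
taxon-group subcommunity after renormalizing within the group, which is
identical to computing H on the subset counts.  Log response ratios
LRR = ln(H_sample / H_initial) cross every post-disturbance sample with
each same-soil initial replicate by default (a replicate-mean variant
exists); pairs with zero or undefined diversity are skipped with a warning,
since the ratio is undefined there.

Bray-Curtis dissimilarity, PCoA, PERMANOVA and SIMPER are implemented from
their definitions rather than wrapped, and are cross-checked in the test
suite against scikit-bio and brute-force enumeration:

- **PCoA** is classical metric scaling (double-centered Gower matrix,
  symmetric eigendecomposition).  Negative eigenvalues — expected for a
  semi-metric like Bray-Curtis — are reported but their axes are dropped
  from the coordinates; no Lingoes/Cailliez correction is applied, and
  explained-variance proportions are taken relative to the positive
  eigenvalue sum.
- **PERMANOVA** partitions the squared-distance matrix with sequential
  (Type-I) sums of squares through projection matrices, so multi-term
  models (disturbance, then time) are supported; significance comes from
  freely permuting sample labels, with the observed statistic included:
  p = (1 + #{F* ≥ F}) / (1 + n_perm), default n_perm = 999.  A residual sum
  of squares that is numerically negative (roundoff around zero) is clipped
  to zero, making pseudo-F = +∞ for perfectly separated designs; ties at
  infinity then count as exceedances, which keeps the permutation p-value
  valid in that degenerate limit.
- **SIMPER** attributes the mean between-group Bray-Curtis to OTUs as the
  average over between-group sample pairs of |x_i − y_i| / Σ_k(x_k + y_k);
  contributions sum exactly to the mean between-group dissimilarity, and
  taxon-group percentages sum to 100.
- **Dissimilarity to initial** is the mean pairwise Bray-Curtis between a
  sample and its soil's initial replicates (self-pairs excluded), chosen
  over distance-to-centroid for consistency with SIMPER's pairwise logic.

## Differential abundance

The responsive-OTU detector is a deliberately reduced negative-binomial
Wald pipeline: median-of-ratios size factors; per-OTU method-of-moments
dispersions (variance = μ + αμ², pooled within groups, with the moment
denominator corrected by −s²/n so the estimator is not biased low at 4+4
replicates); a dispersion trend α(m) = a₀ + a₁/m fitted across OTUs; and
log-scale shrinkage of each dispersion toward the trend with weight λ
(default λ = 10, i.e. the trend carries ten times the weight of the
individual estimate).  The strong default was chosen by simulation-based
calibration: with eight samples the individual moment estimates are so
noisy that near-trend dispersions are required for the Wald z-statistic to
be calibrated (empirical type-I error at nominal 0.05 within the binomial
interval over thousands of null OTUs), the same reasoning that leads
established count-model packages to dominant dispersion priors at small n.
The GLM log μ = β₀ + β₁·group + log s_j is fit by iteratively reweighted
least squares, vectorized across OTUs; the Wald p-value is two-sided
normal.  Shrunken log2 fold changes come from ridge-penalized IRLS
(zero-centered normal prior on the group coefficient, default scale 2 on
the log2 scale).  Benjamini-Hochberg adjustment is the exact step-up.  The
responsive filter keeps q < 0.05 and |log2 FC| > 1 on the shrunken
estimate (shrinkage precedes filtering), splits by sign, and summarizes
counts and mean fold change per taxon group.  Cox-Reid adjusted profile
likelihood, independent filtering and outlier replacement are intentionally
out of scope.

## Stability-landscape recovery model

Community recovery is modelled as the impulse response of a ball in a
basin: displacement of Shannon diversity from the pre-disturbance baseline

    x(t) = D·t·e^(φ₁t) + A·(1 − e^(−φ₂t)),

with perturbation strength D, new-equilibrium displacement A, impulse
decay rate φ₁ (negative for a decaying impulse) and asymptote approach
rate φ₂.  This critically-damped form satisfies x(0) = 0 and x(∞) = A for
decaying rates; an overdamped two-exponential variant is available behind
`form="overdamped"`.  The damping and restoring-force strength of the
underlying second-order system (b = −2φ₁, k = φ₁²) are derived quantities.

The model is fitted per (soil, treatment, taxon group) to per-replicate
displacements at ordinal model times (initial → 0, R0 → 1, …, R170 → 4; a
calendar-day mapping 0/80/82/120/250 is available), with the baseline fixed
at the mean initial Shannon rather than estimated.  Priors are uniform
boxes — D ∈ (0, 10), A, φ₁, φ₂ ∈ (−2, 2) — wide enough to contain every
credible interval the model produces on Shannon-displacement data, plus a
half-normal(1) prior on the Gaussian noise sd with a floor at 10⁻⁴ that
keeps degenerate (constant) trajectories well-posed.  Ambient series are a
null control and are not fitted.

Sampling uses the affine-invariant ensemble sampler with
differential-evolution and snooker moves (80/20 mixture): on this
posterior's curved D–φ₂ ridge the classic stretch move mixes an order of
magnitude slower (integrated autocorrelation ≈ 600–900 steps vs ≈ 150–350),
which is why the package departs from stretch-move defaults.  Defaults are
32 walkers, 20,000 steps, 8,000 burn-in, thinning 4, fixed seed; walkers
start spread over the prior interior.  Convergence is monitored by the
split-chain potential-scale-reduction statistic (walkers as chains,
flagged above 1.05) and autocorrelation-based effective sample sizes.
Fits are bit-reproducible given identical settings.

**Identifiability.**  A and φ₁ (and σ) are sharply identified by this
design.  D and φ₂ share a sloppy likelihood direction: a slower-rising
asymptote (small φ₂) can be compensated by a stronger impulse (large D)
with little change to the curve.  Two measurable consequences, quantified
by the package's own recovery runs (25 time points on [0, 5], 4
replicates, noise sd 0.05): the maximum-likelihood point moves several
percent along the ridge between noise realizations, and the marginal
posterior of D is right-skewed so its median overshoots the generating
value by roughly 5–8% on average even in well-converged chains (the effect
is sampler-independent; doubling walkers and steps reproduces it).  The
recovery utilities therefore report the median over several independent
noise realizations, which suppresses the realization-to-realization wobble
but not the intrinsic skew; recovered A and φ₁ land within 1–2% of their
generating values, D within about 5–10%.  The skewness of the A posterior
is itself a reported diagnostic: a negative skew indicates a community
pulled back toward its original state, a positive skew one drifting to an
alternative state.

## Synthetic-community generator

The generator produces data with the statistical structure the analysis
assumes, so every stage is testable without sequencing archives:

- **Species-abundance distribution.**  True proportions per soil are drawn
  once from a lognormal (default σ = 2.5 on the log scale, 5,000 OTUs) and
  shared by that soil's initial replicates.  At these defaults about 0.3%
  of OTUs classify abundant while holding ≈ 35% of the reads, and ≈ 88% of
  OTUs classify rare — the heavy-tailed partitioning typical of fertilized
  field soils.  A broken-stick model was rejected as too even.  The real
  initial communities' abundance distribution is unknown; lognormal is
  this package's choice.
- **Sequencing noise** is multinomial at fixed depth (default 10,000 reads
  for speed; 67,899 — a typical post-rarefaction depth — via
  configuration), since rarefied data are depth-equalized by construction.
- **Disturbance action.**  Each scenario applies taxon-group-level
  log-fold multipliers to the true proportions, time-modulated by the
  normalized magnitude of a stability-landscape recovery curve so that
  community displacement tracks the impulse-response model.  On top of the
  group effect, every OTU receives a fixed per-treatment lognormal jitter.
  The jitter sd is group-specific, and the packaged scenarios give rare
  OTUs a large value (1.2) against 0.25 elsewhere: this emulates
  conditionally rare "seed bank" taxa that bloom strongly after a
  disturbance while others crash — within-group turnover with modest net
  share change, which is what makes rare taxa the dominant contributors to
  between-state dissimilarity.  Effect sizes per treatment were set so the
  realized share trajectories reproduce the qualitative field pattern
  (abundant down, rare up, common roughly steady; ranking
  HE > FL > DR > FR > AMB), with invading OTUs at 10% (FL) and 20% (HE) of
  the post-disturbance community, injected from a disjoint id space with a
  Dirichlet mass split and constant across recovery timepoints.
- **Null control.**  The AMB scenario is constrained to zero effects, no
  invaders and no jitter; its category shares, dissimilarity trajectory
  and LRRs are flat up to multinomial error, which the suite asserts.

What the generator does **not** emulate: taxonomic or phylogenetic
structure, OTU-OTU interactions or compositional correlations beyond the
multinomial, read-level error/chimeras, variable library sizes, or
temporal autocorrelation of replicates.  Passing tests therefore establish
the correctness and calibration of the estimators under the stated
statistical assumptions, not the field conclusions themselves; real-data
quantities that depend on the deposited sequencing archives (absolute OTU
counts per category, exact SIMPER percentages, regression R² values) are
checked in direction only.

## Problem sizes

Defaults are desk-scale by design: unit tests run on communities of
600–5,000 OTUs at depths of 2,000–10,000 reads; recovery runs fit 100
observations per trajectory; the calibration suites use 2,000–3,000
simulated OTUs.  The full pipeline on the packaged scenario (5,000 OTUs,
168 samples, all stages including 16 Bayesian fits) completes in a few
minutes on one CPU.

## Known limitations

- The two-group NB Wald test covers the pairwise timepoint-vs-initial
  contrasts the analysis needs; general design matrices are out of scope.
- PERMANOVA permutes labels freely; restricted/stratified permutation
  schemes are not implemented.
- The stability model fixes the displacement baseline at the mean initial
  diversity; baseline uncertainty is not propagated.
- The D–φ₂ ridge is a property of the curve family at this sampling
  design; denser early-time sampling, not more MCMC, would be needed to
  break it.
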