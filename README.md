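# raresoil

Temporal dynamics of rare and abundant soil bacterial taxa under
environmental disturbances: a tested, reusable analysis pipeline for
disturbance-recovery mesocosm experiments.

Soil microbiotas conditioned by long-term chemical (NCF) or organic (NOF)
fertilization are exposed to drought, flooding, freeze-thaw cycles, heat,
or left ambient, and profiled by 16S amplicon sequencing before the
disturbance and at four recovery timepoints.  The questions this package
answers from such data, for microbial ecologists and soil scientists:
which taxa are part of the rare biosphere and which are abundant; how each
group's diversity and community structure respond to and recover from a
disturbance; which individual OTUs respond; and whether the community
returns to its original equilibrium or settles in an alternative state.

## What it computes

- **Taxon categories** from initial samples, per soil, using 0.01% / 1%
  relative-abundance cutoffs: always/conditionally abundant (AAT, CAT),
  moderate (MT), conditionally/always rare (CRT, ART), conditionally
  rare-and-abundant (CRAT), plus NEW for OTUs absent from every initial
  sample; category-level abundance flux over time (Sankey-ready tables).
- **Diversity**: rarefaction, Shannon index H = −Σ p_i ln p_i per
  taxon-group subcommunity, and pairwise log response ratios
  LRR = ln(H_sample / H_initial) with t-test contrasts.
- **Community structure**, implemented from definitions and cross-checked
  against independent references in the test suite: Bray-Curtis
  dissimilarity, PCoA, multi-term PERMANOVA (sequential sums of squares,
  free label permutation), SIMPER decomposition of between-group
  dissimilarity, and per-sample dissimilarity to the initial state.
- **Responsive OTUs** by a reduced negative-binomial Wald pipeline:
  median-of-ratios size factors, trend-shrunken method-of-moments
  dispersions, vectorized IRLS GLM fits, Wald tests, ridge-shrunken log2
  fold changes, Benjamini-Hochberg adjustment, and the q < 0.05 &
  |log2 FC| > 1 responsive filter with per-category summaries.
- **Stability-landscape model** of diversity recovery — the core model.
  Displacement of Shannon diversity from the pre-disturbance baseline is
  the impulse response of a damped system,

      x(t) = D·t·e^(φ₁t) + A·(1 − e^(−φ₂t)),

  with perturbation strength D, new-equilibrium displacement A and rate
  parameters φ₁, φ₂.  It is fitted in a Bayesian framework (uniform box
  priors, Gaussian likelihood, ensemble MCMC with differential-evolution
  moves), yielding posterior medians, 95% credible intervals, convergence
  diagnostics, and the skewness of the A posterior — negative skew means
  the community is being pulled back to its original state, positive skew
  that it is drifting to an alternative one.
- **Equilibrium regressions**: ordinary least squares of overall-community
  dissimilarity on the rare:abundant abundance ratio, per treatment or
  soil.
- **Synthetic communities**: a generator producing OTU tables with the
  structure the analysis assumes (heavy-tailed lognormal abundances,
  multinomial sampling at fixed depth, group-level disturbance effects
  time-modulated by the recovery model, rare-taxon "seed bank" blooms,
  invading OTUs), so the entire pipeline is testable without sequencing
  archives.

Model-like components are scikit-learn-style estimators
(`TaxaClassifier`, `PCoA`, `NegativeBinomialDE`,
`StabilityLandscapeModel`) with `fit`/`predict`/`fit_transform`,
`get_params`/`set_params` and trailing-underscore fitted attributes; the
module-level functions are thin wrappers over them.

## Worked example

```python
import numpy as np
from raresoil import (
    CommunityConfig, StabilityLandscapeModel, StabilityParams, classify_taxa,
    default_scenarios, generate_initial_community, relative_abundance,
    simulate_disturbance_series, simulate_diversity_trajectory,
)

cfg = CommunityConfig(seed=42)           # 5,000 OTUs, depth 10,000, 4 replicates
table = simulate_disturbance_series(
    generate_initial_community(cfg), default_scenarios(), cfg
)
rel = relative_abundance(table)
asg = classify_taxa(rel.subset_samples(table.initial_samples("NCF")))
print(asg.counts())
```

```
AAT       15
CAT        6
MT       602
CRT     1550
ART        0
CRAT       0
NEW     3827
```

21 of 5,000 OTUs (0.4%) classify abundant yet hold 36.8% of the reads,
while the rare side (CRT plus the NEW OTUs that were never detected in an
initial sample) is 93% of the OTUs holding 9.3% — the heavy-tailed
partitioning the generator is tuned to produce.  (At depth 10,000 a single
read is exactly the 0.01% cutoff, so the strictly-below-cutoff ART class
is structurally empty; it fills in at greater depths.)

Fitting the recovery model to a synthetic trajectory generated from known
parameters (D = 3.63, A = 0.70, φ₁ = −1.46, φ₂ = 1.69; 25 time points on
[0, 5], 4 replicates, noise sd 0.05):

```python
true = StabilityParams(3.63, 0.70, -1.46, 1.69)
traj = simulate_diversity_trajectory(true, np.linspace(0, 5, 25), 0.05, 4, seed=1)
fit = StabilityLandscapeModel(seed=1).fit(traj.times, traj.displacements)
print(fit.posterior_summary().round(3))
```

```
       median  ci_lower  ci_upper
D       3.951     3.420     4.324
A       0.695     0.676     0.749
phi1   -1.429    -1.480    -1.337
phi2    1.195     0.517     1.950
sigma   0.043     0.038     0.050
```

A and φ₁ come back within a couple of percent.  D overshoots by ~9% here:
D and φ₂ share a sloppy likelihood direction (a slower-rising asymptote
trades off against a stronger impulse), so the D marginal is wide and
right-skewed — its generating value still lies inside the credible
interval.  See `docs/methods.md` for the identifiability analysis.

## Command line

```bash
raresoil simulate --n-otus 2000 --depth 10000 --seed 0   # synthetic tables
raresoil classify --counts otu_table.tsv --metadata metadata.tsv --soil NCF
raresoil run-all --config run.yaml                        # full pipeline
```

`run-all` executes every stage (classification, flux, diversity/LRR,
Bray-Curtis/PCoA/PERMANOVA/SIMPER, differential abundance, stability fits,
equilibrium regressions) and writes tidy TSVs, posterior samples, a JSON
summary and a run log; identical configuration and seeds reproduce all
outputs bit-for-bit.

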