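# Methods

## The estimator

A species' long-term (coalescent) effective population size is estimated by
inverting the neutral mutation–drift equilibrium expectation for nucleotide
diversity, E[π] = 2 x Nₑ μ:

    N̂ₑ = π / (2 x μ)

with π the per-site nucleotide diversity, μ the per-site per-generation
de novo mutation rate, and x the ploidy (1 or 2 for everything in scope;
larger values are accepted). The estimate is equivalently half the mean
pairwise coalescence time in generations, so it integrates demography over
roughly the last 4Nₑ generations. Everything downstream is analysed on log
scales, since both Nₑ and its covariates range over orders of magnitude:
natural logs internally, log10 in reports (log–log slopes are base
invariant; intercepts are reported in log10).

### Mutation-rate uncertainty

Per-study rates arrive either with a published 95% CI or with the raw
mutation count and callable-site opportunity. In the latter case a **Wilson
score interval** for the proportion count/opportunity is used: at the rare
event scale of de novo rates (~1e-8) it is asymmetric, keeps a positive
lower bound whenever at least one mutation was seen, and calibrates close
to nominal coverage (measured 93–97% at p = 1e-8, n = 1e9). The exact
Clopper–Pearson interval can be swapped in via the `method="beta"` argument
(module constant `BINOMIAL_CI_METHOD` sets the default).

Multiple studies of one species are combined by an effort-weighted mean —
effort being the number of trios (pedigree studies) or lines × generations
(mutation-accumulation studies); callable sites are deliberately not
folded into the weight. Study SEs are taken as CI half-width / 1.96
(symmetric normal error on the raw rate scale) and propagated as
SE = sqrt(Σ wᵢ²SEᵢ²)/Σ wᵢ; the combined CI is ±1.96 SE floored at zero,
using a normal rather than t reference. A study with neither CI nor counts
is imputed the largest within-species SE (conservative). Studies reporting
a rate of exactly zero carry no log-scale information and are dropped from
the weighted mean with a logged warning; a species with only zero-rate
studies is excluded.

### Diversity

π values from multiple populations are averaged arithmetically, not pooled:
within-population diversity is the comparable quantity when species are
subdivided. Genome-wide and synonymous-site π are treated as equivalent
(the site class is carried through for record keeping only). The Nₑ CI is
obtained by monotone inversion of the μ CI alone — π sampling error is
small relative to μ error with modern genome-scale data and is not
propagated.

Domesticated species are excluded before estimation: their diversity
reflects bottlenecks and artificial selection, not natural drift.

## Heterogeneity (Cochran's Q)

Within each taxonomic group, the log-scale Nₑ variance implied by each CI,
((ln hi − ln lo)/3.92)², feeds an inverse-variance weighted chi-squared
test: Q = Σ wᵢ(xᵢ − x̄)² with x̄ the weighted mean, df = k − 1. A point CI
maps to variance zero and is floored at 1e-6 inside the test so weights
stay finite. The test is exactly calibrated under its null (measured
type-I error 4–6% at α = 0.05); only the fixed-effect Q is provided — no
random-effects τ² estimation.

## Phylogenetic regressions

The Brownian covariance matrix V has Vᵢⱼ = root-to-MRCA depth of tips i, j
and Vᵢᵢ = root-to-tip depth. Trees must be rooted, uniquely labelled,
with branch lengths, and ultrametric to a relative depth tolerance of 1e-3;
worse violations are an error rather than a silent rescale. Pruning to the
species with complete data preserves pairwise path lengths exactly.
Species present in the data but absent from the tree are dropped with a
logged warning.

GLS is computed by Cholesky whitening; σ̂² = RSS_V/(n−k), SEs from
σ̂²·diag((XᵀV⁻¹X)⁻¹), two-sided t p-values with df = n−k, and the reported
log-likelihood is the ML multivariate-normal value. R² is defined against
the intercept-only GLS model under the same covariance (the standard
convention in comparative methods, where no single definition is
universal); adj R² = 1 − (1−R²)(n−1)/(n−k). Designs are built as
intercept + log10 continuous predictors (optionally z-scored for
standardised slopes) + dummy-coded categorical effects with the
alphabetically first level as reference + requested interactions.
Near-singular designs (condition number > 1e12) are rejected.

**Pagel's λ** multiplies the off-diagonal covariances. The ML fit profiles
the likelihood over λ ∈ [0, λ_max]. By default λ_max is the Brownian
ceiling 1: on ultrametric trees the positive-definiteness boundary lies
only marginally above 1 (≈1.002 on simulated Yule trees), the ML estimate
piles up in that sliver in about half of all replicates when the true
signal is Brownian, and those super-Brownian fits systematically deflate
the slope standard errors (measured slope-CI coverage drops from ~95% to
86–91%). Capping at 1 — also the default of the field's most used PGLS
implementation — restores nominal coverage. `lambda_bound="pd"` instead
searches up to the numeric positive-definiteness boundary (found by
bisection), for comparability with analyses that report λ values such as
1.02 or 1.10. The search is a 20-point coarse grid
followed by bounded Brent refinement (tolerance 1e-4 in λ); the grid guards
against local maxima near the PD boundary. ML (not REML) likelihoods are
used throughout, matching the likelihood-ratio usage: the test of λ = 0
uses the 50:50 boundary mixture of χ²₀ and χ²₁ (a test against λ = 1 can be
formed from the same profile). On a star tree the profile is flat; λ is
reported as 0 with p = 1 and a "lambda-non-identifiable" flag. Estimating
a trait's phylogenetic signal is the intercept-only special case.

Calibration, measured by the validation experiments (one fixed 200-tip
Yule tree per condition, 500 trait replicates each): λ̂ is essentially
unbiased at λ ∈ {0, 0.5, 1} (mean error < 0.05), and the slope's 95%
t-interval covers the truth at 93–97% in all three conditions under the
default λ ≤ 1 bound. Under `lambda_bound="pd"` coverage at the Brownian
boundary degrades to ~86–91% (tree-dependent) for the reason given above;
users needing super-Brownian λ estimates should treat slope intervals
from such fits with caution. Conditioning on a point λ̂ always ignores its
uncertainty — a limitation shared by standard PGLS implementations — but
away from the PD boundary its measured effect on coverage is within
Monte-Carlo error.

## Derived predictors

Propagule size for mammals lacking direct estimates:
adult body length × (weaning mass / adult mass)^(1/3) — the cube root
converts a mass ratio into a linear-dimension ratio under isometry. Census
size proxy: range area × density. Density proxy: range area / adult body
mass (leaning on the macroecological density–body-size relationship).
πN/πS measures the proportion of effectively neutral nonsynonymous
variation. All are unit-checked pure functions; units are normalised at
ingest (g, cm, km²), and only log–log slopes — which are unit-free — are
interpreted downstream. A log–log slope b converts a k-fold change in the
predictor into a k^b-fold change in the response (e.g. slope 0.09 turns a
10-fold census increase into a 1.23-fold Nₑ increase).

## Synthetic data generator

The generator emulates the *structure* of a literature-compiled
comparative study, with full ground truth:

* **Tree** — Yule (pure birth), rescaled to unit root-to-tip depth;
  deterministic per seed. One global seed spawns independent substreams
  for tree / traits / observations.
* **Traits** — log10 predictor ~ MVN(0, V) (Brownian, rate 1);
  log10 Nₑ = β₀ + β₁·log10 predictor + ε with ε ~ MVN(0, σ²V_λ).
* **Observations** — species μ ~ 10^N(mean, sd); per-study counts
  ~ Poisson(μ · callable_sites) (negligible error vs the binomial at these
  rates, and cheap), reported with a Wilson CI and a random integer effort;
  true π = 2xNₑμ, observed as ≥ 1 log-normally perturbed values with a
  mean-one perturbation of coefficient of variation `pi_obs_cv`.
  `exact=True` switches every noise source off for machine-precision
  recovery tests.

Defaults are study-scale conditions chosen once: 200 tips, λ = 0.9,
β₀ = 5.0 (log10 Nₑ centred near 10⁵), β₁ = −0.5, σ² = 0.2,
μ ~ 10^N(−8.5, 0.3), callable_sites = 1e10 (callable genome × trios/lines:
expected counts of order 30–300 per study, as in real pedigree/MA data),
2 mutation studies and 2 π estimates per species, pi_obs_cv = 0.1, 6% of
species flagged domesticated, 10% asexual. Taxonomic groups are contiguous
tip blocks in tree order (clade-like); reproductive mode and domestication
are drawn independently of the traits. What the generator does **not**
emulate: correlated study biases (reference-genome or pipeline effects on
μ), population structure inflating range-wide π, uneven data availability
across clades, and trait measurement error. Passing tests therefore
demonstrate correctness of the estimators and calibration of the tests
under the stated model, not robustness to those real-data pathologies.

## Pipeline conventions

Medians use the midpoint convention for even group sizes. Log-normal
distribution fits (MLE: mean and population SD of logs) are reported only
for groups with ≥ 10 species. The split-half validation — which breaks the
artefactual correlation between N̂ₑ and π that arises when the same π is
used on both axes — assigns each species' π estimates alternately to two
sets after sorting by population label (deterministic; a seeded random
split is available), builds N̂ₑ from one set and regresses the other set's
log π on it, in both directions. Every excluded row is logged with a
machine-readable reason code; outputs are sorted by species_id so re-runs
are byte-identical.

## Problem sizes in the validation suite

The self-calibration experiments use: 200 species for exact-recovery and
λ-recovery runs (500 replicates per λ condition), 10,000 null replicates
(k = 10) for Q calibration, and 2,000 replicates for Wilson coverage —
sizes at which the Monte-Carlo error on a 95% coverage estimate is about
±1%, small against the 93–97% acceptance bands.
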