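# Methods

## The experimental design and the trait matrices

The package models a germination trial in which every population is exposed
to four stratification regimes — none, 3 weeks at 3 °C, 8 weeks at 3 °C,
3 weeks at 30 °C — crossed with two day/night incubation regimes (20/10 °C
and 25/15 °C), with four replicate 25-seed plates per cell.  Three factors
index the treatments: stratification length SL ∈ {0, 3, 8} weeks,
stratification temperature ST ∈ {3 °C, 30 °C, none}, and incubation regime
IT.  The design is deliberately non-crossed: ST is "none" exactly when
SL = 0, and this asymmetry propagates into every downstream model (aliased
GLM columns, zero-contribution GLMM terms).

Germination is viability-adjusted per plate: the denominator is
`germinated + cut-test-filled`, i.e. only seeds with a demonstrably intact
embryo count.  Plates with zero viable seeds become missing values and are
excluded from replicate means rather than counted as zeros; a population
missing *all* replicates of a treatment is an error, because the trait
matrix would have a hole the distance computations cannot absorb.  Trait
cells are means of per-plate proportions, not pooled counts — the two
differ whenever viable counts differ between replicates, and the
mean-of-proportions convention weights each plate equally.  Total
germination includes seeds that germinated during (warm or cold)
stratification; a switch (`include_warm_strat_in_total=False`) excludes the
warm-stratification germinants for users who prefer the narrower reading.
The 3-trait during-stratification matrix covers only the three stratified
regimes — the unstratified control has no stratification period, so a
fourth column would be identically zero and would only dilute the distance
structure.

## Phylogenetic matrices

From a rooted, dated tree the package derives (i) cophenetic distances
(path lengths between tips, in the tree's time units) for the Mantel
tests, and (ii) the relatedness matrix **A**, whose (i, j) entry is the
branch length shared from the root to the MRCA of tips i and j.  **A** is
scaled to unit diagonal so that it is a correlation matrix and the GLMM's
`sigma^2` is interpretable as the full coefficient variance; the scaling
choice is exposed (`scale=False` returns raw shared depths).  For
non-ultrametric input each pair is normalized by the geometric mean of the
two tip depths, with a warning, rather than rejected.  On ultrametric
trees the identity `d(i,j) + 2·sharedDepth(i,j) = depth(i) + depth(j)`
holds exactly and is part of the test suite.

## Bioclim variables

Seven summaries are computed from 12-month tmin/tmax/precipitation series:
BIO1 (mean annual temperature, °C), BIO2 (mean diurnal range, °C), BIO4
(temperature seasonality, sd × 100), BIO8 (mean temperature of the wettest
quarter, °C), BIO12 (annual precipitation, mm), BIO15 (precipitation
seasonality, %), BIO18 (precipitation of the warmest quarter, mm).
Quarters are consecutive 3-month windows with December–January wrap-around
(12 candidate windows; ties go to the earliest window).  Standard
deviations use the population (n) denominator, and BIO15 divides by
`1 + mean` monthly precipitation — both conventions match the widely used
`biovars` implementation, and BIO15's `+1` guard (switchable in principle,
documented here) prevents division blow-ups at arid sites.  Before distance
computation the bioclim table is log-transformed to even out scales;
temperatures can be ≤ 0 °C, so any column with a non-positive minimum is
shifted by `1 − min` (smallest value maps to log 1 = 0) with a loud
warning.  This offset rule is a declared package convention for a step the
source analysis leaves unspecified.

## Mantel tests

The statistic is the Pearson correlation over strictly-lower-triangle
entries of two labeled distance matrices; the null distribution comes from
jointly permuting rows and columns of the second matrix.  The p-value is
one-tailed (upper) with the add-one convention
`p = (1 + #{r_perm ≥ r_obs}) / (1 + B)`, B = 10000 by default; an
exhaustive mode enumerates all n! relabelings for n ≤ 8 and is exact.  The
default seed (20150801) is recorded in every result object.

Comparing an 8-species phylogeny with 24-population trait matrices
requires a choice: the package expands species distances to population
pairs with conspecific distance 0 (default), and also offers averaging
traits to species level first (`species_mean` mode).  Expansion keeps the
population-level signal in the trait matrix while placing all conspecific
pairs at phylogenetic distance zero; it is the only construction that
makes the population-level test well-posed, but it does treat conspecific
populations as phylogenetically identical.

## The spike-and-slab phylogenetic GLMM

Counts are binomial with logit link.  The linear predictor for species i,
population j under treatment (sl, st, it) sums a species intercept and ten
indicator-gated terms: P, SL, ST, IT and their six pairwise interactions,
each with per-level coefficients and a per-species indicator δ.  Terms
bearing ST contribute 0 for unstratified cells (no "none" coefficient is
estimated) — the design never crosses SL = 0 with a stratification
temperature, so giving "none" its own coefficient would add a parameter
the data cannot see apart from its prior.

Priors: P(δ = 1) = 0.5 per main factor and species; interaction indicators
are conditioned on both parents being included (a child is forced to 0
otherwise, and the joint prior keeps each main factor's marginal at 0.5).
Population-dependent coefficient families (P, P:SL, P:ST, P:IT) are iid
N(0, 1).  Species-level families (the intercept, SL, ST, IT, SL:ST, SL:IT,
ST:IT) are multivariate normal across species, level by level, with mean a
N(0, 1) hypermean (fixed at 0 for interaction families) and covariance
`sigma^2 A`; each family has its own `sigma^2` with
`1/sigma^2 ~ Gamma(0.1, 0.1)`.  The species intercept carries the
`sigma^2 A` prior like the other species-level families and has no
indicator.  The factor coding is deliberately overparameterized (per-level
coefficients, no reference level), exactly as the model equation is
written; propriety comes from the priors.

### Sampler

A purpose-built Metropolis-within-Gibbs scheme:

* **Coefficient columns.**  Species-level families update one level-column
  at a time by blocked random-walk Metropolis with proposals shaped by the
  Cholesky factor of A (target acceptance 0.23); population-level columns
  update all populations at once with per-population accept/reject (valid
  because the prior is iid and each cell belongs to one population; target
  0.44).  Scales adapt by Robbins–Monro during the adaptation phase only.
* **Hypermeans and variances.**  Exact conjugate Gibbs draws.
* **Indicator flips.**  A flip jointly proposes the gated coefficient
  block.  Turn-on proposals draw the block from a Laplace (one-block
  penalized IRLS) approximation of its conditional posterior given the
  rest of the linear predictor — diagonal, since each cell touches exactly
  one coefficient of a block — with the exact Hastings correction; the
  acceptance probability then approximates the true posterior odds of the
  two models (a Savage–Dickey-like behaviour).  A 20% share of plain
  conditional-prior flips is mixed in for exploration.  Flips respect the
  hierarchy: a parent cannot leave while a child is in, a child cannot
  enter unless both parents are in, and the prior-ratio bookkeeping
  accounts for children whose conditional prior opens or closes.
* **Recentering (fiber) move.**  The overparameterized coding leaves exact
  posterior ridges: a block's mean is collinear with the species
  intercept, an ST shift with the stratified SL levels, interaction means
  with their parents.  Without help, null blocks absorb identified
  structure through these unidentified directions and can never be turned
  off.  Once per iteration and species, all of that species' coefficients
  are redrawn from their joint Gaussian prior *conditioned on the per-cell
  linear predictor staying fixed* (Matheron conditioning with a
  pseudo-inverse for the rank-deficient constraint).  The likelihood is
  untouched, so this is a Gibbs update of the unidentified fiber
  coordinates; it moves redundant structure between blocks the way the
  prior expects, in one step instead of by slow random-walk diffusion.
* **Adaptation phase.**  Runs with every indicator on (the full model) so
  proposal scales are tuned for every block; flips begin at burn-in.
  Adaptation draws are discarded.

Chains are independently seeded from a `SeedSequence` spawn of the user
seed; runs are bit-reproducible.  Default settings mirror a study-scale
run (4 chains, 5000 adaptation, 5000 burn-in, 50000 samples, thinning 10 —
thinning keeps the retained 20000 draws desk-scale; thin = 1 recovers the
full 200000).  The correctness and recovery checks in the test suite use
deliberately smaller chains (4 × 5000–6000 retained after 500–1000
adaptation/burn-in), which the mixing moves above make sufficient: on an
exactly enumerable 1-species toy the sampler matches a Gauss–Hermite
quadrature oracle to ~0.003, and on the full 24-population design it
recovers a planted stratification-length signal (inclusion 1.0 when the
effect sd is 2, ≤ 0.02 when absent).

Summaries: the inclusion table is the posterior mean of each δ per species
with Monte-Carlo standard errors (variance / ESS) and split-R-hat per
indicator; a table is flagged unconverged if any R-hat exceeds 1.1.  The
phylogeny-necessity check reports the posterior probability that *no*
species includes the population factor — zero means population structure
is never explained away by phylogeny alone.  The during-stratification
refit runs the identical machinery on germination-during-stratification
responses; IT is retained by default (plates physically differ by their
assigned incubation regime) and can be dropped via
`ModelSpec(families=...)`.

## Per-species stepwise-AIC GLMs

For each species, plate-level counts (four replicates as separate binomial
observations — the per-plate convention changes the binomial constant and
hence absolute AIC, and is the one that reproduces conventional printed
values) are fitted by IRLS binomial logit GLMs (statsmodels backend).  The
factor coding follows R's `glm`: treatment contrasts with the
alphabetically first level as reference, ST a three-level factor
{3, 30, none}, and design columns that are aliased in the observed
non-crossed design dropped left-to-right, so `k` is the design-matrix
rank.  AIC and log-likelihood are coding-invariant, and the rank
convention is pinned by structural tests (e.g. the maximal final-
germination model for a 4-population species has k = 23; the
during-stratification models, fitted on the three stratified treatments
only with SL ∈ {3, 8} and ST ∈ {3, 30}, give k = 3 for P+SL with two
populations).  The log-likelihood includes the binomial coefficient term
so AIC values are comparable across software.

The search is greedy bidirectional stepwise AIC from a common maximal
model (all four factors and six interactions for total germination;
P + SL + ST and their interactions for during-stratification), moving to
the best single-term neighbour that respects marginality and stopping at a
local minimum.  Every model evaluated along the way becomes a candidate;
Akaike weights are normalized per species by default, with a pooled mode
(`pool_candidates=True`) that renormalizes over the union of structures
visited across species.  Reporting filters to ΔAIC < 2.  Quasibinomial
refits are out of scope for selection (AIC is undefined under
quasi-likelihood); a Pearson dispersion estimate is reported with each fit
instead.

## Synthetic data

The generator is the GLMM's generative model run forward under the study
design constants: a pure-birth tree with root depth 1 (tips sp1…spN), the
relatedness matrix from it, species-level coefficient families drawn
MVN(hypermean, sigma^2 A) per level, population effects N(0, sd), a
configurable true-indicator pattern (default: drawn from the hierarchical
Bernoulli(0.5) prior), inverse-logit cell probabilities, and two-stage
binomial sampling — filled ~ Binomial(25, fill rate 0.9), then germinated ~
Binomial(filled, p) — so viability adjustment is exercised end to end.
The split of germinants between the stratification and incubation periods
is an independent Bernoulli thinning with regime-specific fractions
(0.3/0.4 for cold, 0.6 for warm stratification, 0 for the control), a
modelling convenience rather than a biological claim.  Monthly climate
emulates the target region: mean annual temperatures of 2–16 °C, annual
precipitation 180–560 mm, and a per-site mixture weight between a
July–August monsoon profile and a December–February winter profile, so
precipitation seasonality genuinely varies across sites.

What the simulations do *not* emulate: overdispersion beyond binomial
(real plates are often extra-variable), time-to-germination dynamics,
dormancy-class mechanisms, non-stationary climate, and measurement error
in the cut test.  Passing recovery tests therefore demonstrate the
estimators work when their assumptions hold, not that real germination
data meet those assumptions.

## Numerical choices and degenerate inputs

* A receives a 1e-10 diagonal jitter before Cholesky/inverse; PSD is
  checked with tolerance 1e-8.  Ultrametricity tolerance is 1e-6
  (relative).
* Binomial log-likelihoods use `log1p`-safe softplus throughout; cells
  with n = 0 contribute exactly zero, which is also how prior-only runs
  are expressed.
* Zero-variance distance triangles raise (`degenerate matrix`) rather
  than return r = NaN.
* Window ties in BIO8/BIO18 go to the earliest window; replicate order
  never affects trait cells; records order never affects any output.
* GLM separation is detected heuristically (|coef| > 15) and flagged
  `converged=False` with a warning rather than raised, since stepwise
  search must be able to pass over such candidates.
* The stepwise search caches fits by term set, so the returned candidate
  set contains each structure once.

## Known limitations

* The Mantel expansion places conspecific populations at distance zero; a
  within-species phylogeny would refine this but is outside the package's
  inputs.
* Inclusion probabilities are posterior means of binary chains; with very
  sticky indicators the MCSE/R-hat diagnostics flag the problem but cannot
  repair it — longer chains are the remedy.
* The GLM stepwise search is greedy; it logs every candidate it visits,
  but a better model outside its path will be missed (the test suite
  checks it attains the exhaustive optimum on small spaces).
* Absolute AIC values depend on the per-plate aggregation convention;
  comparisons across conventions are meaningless even though rankings
  within a convention are stable.
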