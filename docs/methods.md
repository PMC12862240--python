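# Methods

`seedlingndd` analyses seasonal woody-seedling survival in a mapped forest
plot as a function of neighborhood crowding, habitat, and seasonal rainfall,
and ships a synthetic forest generator whose ground truth exercises every
stage of the pipeline.  This note records the models, the numerical choices,
and the design decisions taken where the problem was genuinely open.

## The survival model

For seedling *i* in quadrat *j* during census interval (year) *k*, survival
over the interval is Bernoulli with

    logit p_ijk = β0 + β·x_ijk + γ_species(i) + φ_j + μ_k

where the fixed-effect vector x contains, all standardized within the
seasonal subset being fitted: log initial height; conspecific seedling
density S_con (same-species seedlings sharing the 2 m × 2 m quadrat, focal
excluded); conspecific adult crowding A_con = Σ BA_i / max(d_i, d_min) over
conspecific stems with DBH ≥ 1 cm within 20 m of the quadrat centre (BA in
m², d in m); the four heterospecific crowding sums S_TOTPd, A_TOTPd,
S_TOTFd, A_TOTFd = Σ distance(focal, sp) × abundance_sp over heterospecific
neighbors (phylogenetic or functional distance; seedling neighbors share the
quadrat, adult neighbors lie within 20 m); canopy openness; the first three
principal components of topography + soil; and the seasonal rainfall total
of the interval.  γ, φ, μ are independent Gaussian random intercepts for
species, quadrat, and census year.  The model is fit separately for dry
(November–April, labelled by starting year) and rainy (May–October)
intervals, pooling years within a season.  A residual term has no role in a
Bernoulli likelihood and none is included; dispersion is assessed post hoc.

Positive coefficients on the TOT distances mean survival improves with more
phylogenetically/functionally distant neighborhoods, i.e. phylogenetic or
functional negative density dependence.

## Fitting: Laplace maximum likelihood

No installed Python package fits frequentist Bernoulli GLMMs with crossed
random effects, so the fitter is implemented here (`glmm.py`), following the
lme4 formulation: random effects are scaled spherical coordinates
u = Λ(θ) b, b ~ N(0, I).  For trial variance parameters θ, (β, b) are
maximized jointly by penalized Newton iterations (PIRLS; the crossed-factor
Hessian is assembled by `bincount` scatter sums and solved densely, a few
hundred coefficients at most), giving the profiled Laplace criterion
ℓ(θ) = loglik(ŷ) − ‖b̂‖²/2 − ½ log det(Λ'Z'WZΛ + I), optimized by L-BFGS-B
with the Cholesky diagonal bounded at zero.  At θ̂, β is then pushed from
its PIRLS-profiled value to the true maximizer of the Laplace objective with
an exact analytic gradient (the log-determinant depends on β through the
working weights; the implicit mode shift enters via the envelope theorem).
On shared test problems the results agree with lme4's default `glmer`
(nAGQ = 1) to ~1e-4 in coefficients and ~3e-4 in log-likelihood, and with
`glmer(nAGQ = 0)` to ~1e-5 when the refinement stage is disabled.
Convergence tolerances: inner gradient < 1e-10 (relative), outer ftol 1e-11.
Wald covariance of β comes from the joint (β, b) Hessian at the optimum,
conditional on θ̂ — the standard approximation, which understates
uncertainty in coefficients of covariates that vary only across a handful of
grouping-factor levels (see *Known limitations*).

Species-specific sensitivities use a correlated random intercept + slope
for species, one predictor at a time (a joint multi-slope model would be
fragile at study scale); the species coefficient is the fixed slope plus the
conditional mode, its CI from the conditional-mode SD, and the slope term is
tested by a 2-df likelihood-ratio test (conservative at the variance
boundary).  Seasonal contrasts are paired t-tests on species matched across
seasons, BH-FDR-adjusted over the predictors tested; trade-offs are
unweighted OLS of one sensitivity on another.

Diagnostics: Nakagawa R² on the latent-logit scale (residual variance
π²/3; the random-effect variance is averaged over rows, which generalizes
the sum-of-variances formula to random slopes); Pearson dispersion ratio
with a parametric-bootstrap p-value (default 250 draws; two-sided).  For
binary data the Pearson ratio deviates from 1 only through mean
misspecification, so the check guards against structural lack of fit rather
than classical extra-binomial variation.

Relative importance is hierarchical partitioning on marginal R²: every
subset of predictor units is re-estimated and each unit's share is its
averaged R² increment over all entry orderings, normalized to 100%.  By
default units are the four predictor groups (height / biotic / habitat /
rainfall, 16 refits) and the subsets re-estimate (β, u) at the full-model θ̂;
per-predictor partitioning and full θ re-optimization are opt-in.  More than
14 units is refused (2^k refits).

## Bespoke predictors

* **Topography** — quadrat elevation is the mean of the four subplot-corner
  elevations; slope is the mean dip of the four planes through corner
  triples, from exact 3-D triangle normals; convexity is focal elevation
  minus the mean of the eight neighboring quadrats.  For edge quadrats the
  rule is centre-point elevation minus the quadrat's own corner mean — with
  corner-only data the two coincide and edge convexity is zero, so an
  optional DEM callback supplies a true centre sample when available.
* **Habitat PCA** — topography + soil variables are z-scored and
  eigendecomposed (SVD); canopy openness stays out and enters the model on
  its own.  Components are oriented so the largest-|loading| entry is
  positive, making output bit-reproducible.  The PCA is recomputed per
  seasonal subset because the quadrats holding live seedlings can differ
  between seasons.
* **Distances** — phylogenetic distances are cophenetic path lengths on the
  study tree.  Functional distances default to the cophenetic matrix of a
  UPGMA dendrogram built on Euclidean distances over the nine z-scored leaf
  traits; a direct-Euclidean alternative is selectable because published
  descriptions of trait-dendrogram workflows are ambiguous between the two.
  Species are sorted lexicographically before clustering so merge ties are
  deterministic.  Traits enter untransformed before z-scoring; a config flag
  can log-transform designated traits.
* **Crowding conventions** — distances are measured from the quadrat centre
  (the unbiased single-point summary of a 2 m quadrat); the inverse-distance
  weight in A_con is floored at d_min = 0.5 m so an overhanging stem cannot
  dominate; adult "abundance" in the TOT sums is the stem count within the
  radius (basal-area weighting is the separate A_con construct); neighbor
  sets use the census at the start of each interval so predictors precede
  outcomes; truncated neighborhoods at the plot edge are flagged, not
  corrected.
* **Radius choice** — the adult-neighborhood radius is selected by refitting
  the full model with adult metrics rebuilt at 5, 10, 15, 20 m and taking
  the lowest AIC; exact ties break to the smallest radius.

## The synthetic community

The generator emulates the study conditions: a 200 m × 200 m plot gridded
into 100 subplots of 20 m × 20 m, each nesting one 2 m × 2 m seedling
quadrat at its northeast corner; 56 species; a mean of 9.36 seedlings per
quadrat (~936 seedlings); four census intervals alternating dry/rainy from
late 2020.  Components:

* **Phylogeny** — pure-birth (Yule) tree, simulated forward with exponential
  waiting times and extended past the last speciation so terminal branches
  are never zero; ultrametric by construction.
* **Traits** — nine independent Brownian-motion traits along the tree
  (abstract units; standardization removes scale downstream).
* **Terrain / soil / canopy** — a smooth sinusoid-mixture surface with a
  south-to-north trend, amplitude 15 m; ten soil variables from a low-rank
  spatial factor model whose first factor is the standardized quadrat
  elevation (so the habitat PCA's leading axis tracks elevation, as in the
  field data) plus Gaussian-process factors with 40 m range; canopy openness
  as a logistic transform of another smooth field, typically 5–40%.
* **Stems** — a Thomas cluster process per species (parents uniform,
  offspring Gaussian with 10 m scale, wrapped toroidally so realized
  intensity is unbiased), overall intensity 0.25 stems/m² (~10,000 stems
  with DBH ≥ 1 cm), geometric rank-abundance across species, left-truncated
  lognormal DBH.
* **Survival** — drawn from the model above, with the design matrix built by
  the same habitat/distance/neighborhood modules the inference side uses.
  True coefficients are seasonal: the defaults place the community-level
  effects at the published point estimates (canopy +0.315 in the dry season;
  seedling phylogenetic crowding +0.939, adult functional crowding +0.681
  and rainfall −0.412 in the rainy season) and zero elsewhere; random-effect
  SDs default to species 0.5, quadrat 0.3, year 0.2 — field-typical values
  chosen once, as the source data do not report variance components.
  Optional per-(species, season) slope deviations inject known slope
  heterogeneity for the species-level recovery tests.  Recruitment is an
  optional Poisson process per quadrat-interval, off by default (the
  survival model conditions on present seedlings).

**Standardization symmetry.**  Within a season, later-interval membership
depends on earlier survival, so a season-pooled scaling cannot exist before
outcomes are drawn.  The generator therefore standardizes with the season's
first-interval cohort (rainfall, constant within a cohort, is scaled by the
configured per-interval totals) and stores that scaling in the study truth.
The inference side standardizes over its fitted subset, as it must with real
data.  Truth comparisons are made on the raw per-unit scale — the true value
of an inference-standardized coefficient is β_true · s_inference /
s_generator, which is exact under any linear rescaling — so the two
conventions never bias recovery checks.

**What the generator does not emulate:** growth, size-dependent mortality
beyond the height covariate, pathogen/herbivore mechanisms (density
dependence is imposed phenomenologically through the coefficients), spatial
autocorrelation of survival beyond the quadrat intercept, measurement error
in traits or topography, and observed seedling aggregation (cluster
parameters are free knobs, not calibrated to the plot).  Passing recovery
tests therefore demonstrates that the estimation machinery is correct under
the stated model, not that the model is adequate for any particular forest.

## Problem sizes used in validation

The test suite and the acceptance script choose deliberately modest problem
sizes: oracle comparisons run on ≤ 1,000-element instances; the GLM-limit
check simulates at 4× seedling density (~5,800 rows) where boundary variance
estimates are clean; parameter recovery runs 50 replicates at 5× density
with 8 census intervals — four year levels per season, following the design
decision that year-level variance components need more than the study's own
2–3 levels to be estimable; dispersion calibration uses ~20 replicate
datasets with 50-draw bootstraps; the acceptance script runs the full
pipeline at default study scale with a 200-draw dispersion bootstrap and a
10-replicate recovery block.

## Known limitations

* Rainfall varies only across year levels within a season.  With few year
  clusters its Wald CI undercovers (≈75–85% at nominal 95% in recovery runs
  with four year levels) — a small-cluster property shared by the standard
  mixed-model tooling, not an implementation defect; pooled coverage across
  all coefficients is ≈94%.  Inference on rainfall from a handful of
  seasonal totals should be treated as descriptive.
* Laplace approximation error is visible in the third significant figure of
  the log-likelihood on very small clusters; adaptive quadrature would be
  needed for higher accuracy (single-factor numerical integration is
  implemented only as a test oracle).
* The LRT for random slopes uses a χ²(2) reference, conservative at the
  variance boundary.
* No spatial autocorrelation structure beyond the quadrat intercept; no
  phylogenetic covariance among species effects; no Bayesian alternative.
* The edge-quadrat convexity default (zero without a DEM callback) follows
  from defining the centre elevation as the corner mean; analyses sensitive
  to edge convexity should supply a DEM.

One further validation detail: the adult-radius AIC scan only carries signal
when the generating model has a real adult-density effect; with the default
(null) A_con coefficient the scan's AIC differences are noise and the
selected radius is arbitrary, which is the scientifically correct behaviour.
The scan-recovery test therefore injects A_con = −0.8 at the generating
20 m radius and checks the scan selects 20 m in the majority of replicates.
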