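# Methods

This note records the statistical models, conventions, and design choices
behind `phyloallom`, in enough detail to audit any number the package
produces.

## Trees and covariance structures

A phylogeny is a rooted tree with branch lengths in millions of years (my);
the analyses assume a time-calibrated (ultrametric) tree, checked with a
relative root-to-tip-depth spread tolerance of 1e−6 because dated consensus
trees carry rounding.  The Brownian-motion (BM) covariance matrix `C` has
`C[i,j]` equal to the shared root-to-MRCA path length and `C[i,i]` the
root-to-tip depth.  Model transforms are applied to `C`, not to branch
lengths, so they compose cleanly with the trait models:

- **Pagel's λ** multiplies off-diagonals by λ ∈ [0, 1]; λ = 0 is the star
  (independent-species) model, λ = 1 plain BM.
- **Ornstein–Uhlenbeck (OU)**, scalar α > 0, *fixed-root* form:
  `C'[i,j] = e^{−α(tᵢ+tⱼ−2tᵢⱼ)}·(1−e^{−2α tᵢⱼ})/(2α)` with `tᵢⱼ` the shared
  path length.  The fixed-root (non-stationary) form is used because the
  trees are calibrated from a root; it requires an ultrametric tree and the
  code refuses otherwise.  A stationary form would be a straightforward
  alternative but is not implemented.
- **Early Burst (EB)**, r ≤ 0: `C'[i,j] = (e^{r tᵢⱼ}−1)/r`, computed with
  `expm1` so the r → 0 limit equals BM exactly.

Tip labels are matched to trait tables by trimming, collapsing
whitespace/underscores and case-folding.  Species missing from the tree are
a hard error that lists the offenders; extra tips are pruned with the
dropped labels recorded in the tree metadata.  Pruning follows the
`ape::drop.tip` convention: the stem above the retained species' MRCA is
removed.

## Trait summaries

Volumes are mm³ internally (cm³ accepted on load and converted); body mass
is grams.  Species summaries use the median and the **raw** median absolute
deviation — no 1.4826 normal-consistency factor — because variability is
reported as MAD as a percentage of the median (MAD%), and the published
variability values are consistent with the raw form.  MAD% is reported only
for species with ≥ 4 observations (spread from 1–3 specimens is noise); the
bundled table also carries the printed MADs of the two n = 2 species.

Outlier screening is two-stage: Shapiro–Wilk normality p-values and
±1.5 IQR boxplot flags are always computed for species×trait cells with
n ≥ 4, but flagged specimens are excluded only when the caller opts in.
Ratio tables divide species medians and display 2 decimals rounded half away
from zero (the convention the verified printed cells follow); unrounded
values are kept alongside.  For species with several specimens the median of
per-specimen ratios (with its MAD) is also reported, which is what the
source table prints for those species — it is *not* recomputable from the
medians, and the curated verified-cell list therefore covers only
single-specimen cells whose printed ratios agree exactly with the printed
medians.  A handful of printed cells evidently computed from unrounded
volumes (they differ in the last decimal) are marked non-recomputable and
never forced to match.

The encephalization quotient uses the classic mammalian reference
`EQ = brain / (0.12 · P^{2/3})` (P = body mass; coefficient and exponent
overridable for other conventions).  Standardized brain–body residuals are
OLS residuals of log brain on log body divided by the residual SD.

## Evolutionary model fitting

Traits (log₁₀ volumes) at the tips follow a matrix-normal model: stacked by
trait, `vec(Y) ~ N(z₀ ⊗ 1, R ⊗ C(θ))`, with `z₀` the root states, `R` the
among-trait covariance, and `C(θ)` the transform above.  Estimation is ML
with the n-divisor (joint ML is required for AIC comparability; PGLS
standard errors use the usual n−p divisor instead, see below).

With complete data and a single shared `C`, `z₀` (GLS mean) and `R`
(n-divisor cross-product of whitened residuals) have closed forms, so the
likelihood is profiled over the single shape parameter: a coarse grid
(λ ∈ {0, .25, .5, .75, 1}; log-spaced α and r scaled by tree depth) followed
by bounded scalar refinement with tolerance 1e−8 on lnL.  If refinement ends
below the best grid point the grid optimum is kept and the fit is flagged
unconverged rather than silently reported.

Missing trait values (e.g. ansiform volumes for 21 of 34 species) are
handled *exactly* by deleting the corresponding rows/columns of the stacked
`R ⊗ C` covariance; `z₀` and the Cholesky factor of `R` are then optimized
numerically (L-BFGS-B, bounded, warm-started from the complete-case closed
form).  This differs from the EM approach of R's Rphylopars, so multi-trait
AIC values on real data reproduce approximately, not bit-exactly.

Per-trait OU ("ou-diag") is implemented as independent single-trait OU fits
(diagonal `R`, one α per trait).  The full multivariate-α OU — the
worst-ranked model in the motivating analyses — is out of scope.

Parameter counts for AIC (2k − 2 lnL, an identity of the fit object):
p root states + free entries of `R` (p(p+1)/2, or p when diagonal) + shape
parameters (0 for fixed-λ models, 1 for λ/α/r, p for per-trait α).  The
λ = 1 vs λ = 0 χ² contrast compares two fixed hypotheses with equal k; df = 1
is adopted as a convention and echoed in the result.

## Ancestral character estimation

Under BM the joint-ML reconstruction of internal states minimizes
Σ (Δ branch)²/length, a quadratic problem whose normal equations are the
branch-weighted graph Laplacian restricted to internal nodes; the root row
equals the GLS root state.  Node variances are `σ̂²` times the diagonal of
the inverse restricted Laplacian, which equals the universal-kriging
variance with the root profiled out (verified against the dense formula in
the tests); `σ̂²` is the ML rate of the supplied BM fit.  95% CIs are
estimate ± 1.96 SD on the log scale and are exponentiated for the mm³
columns, matching the log-trait workflow.  Zero-length internal branches are
clamped to 1e−10 my in the weights.

## PGLS, isometry, grade shifts

PGLS solves the whitened least-squares problem for `y = a + b·x`; standard
errors use `σ̂² = RSS_C/(n−2)` and CIs use t(n−2) quantiles — at n = 13 the
difference from normal quantiles is material.  The covariance defaults to BM
and accepts any transform tag or a precomputed matrix.  The predictor is
always the larger reference structure (cerebral or rest-of-cerebellum
volume, the latter computed as cerebellum − ansiform, never assumed
supplied).  Isometry is classified from the slope CI at 95% and 99%
separately (CI above 1 → hyper-allometric, below → hypo-allometric); the
two levels are never collapsed.  The slope-CI interpretation is used for the
calls; mean-response bands are a display concern only.

Phylogenetic ANCOVA extends the design with a group indicator
(vary="intercept"), a group×x interaction ("slope"), or both, and compares
restricted vs full models by `F = [(RSS_r − RSS_f)/Δp]/[RSS_f/(n − p_f)]` in
the whitened space with `Pr(>F)` from `F(Δp, n − p_f)`.  Both groups need
≥ 2 species and must partition the sample.  `R²_lik = 1 − exp(−(2/n)(lnL −
lnL_null))` uses ML likelihoods (null = intercept-only GLS, same C);
Fisher's r-to-z contrasts `r = √R²_lik` between groups with variance
`1/(n₁−3) + 1/(n₂−3)`, refusing groups with n ≤ 3.  Clade-restricted reruns
(e.g. haplorhines only) are a species filter, not separate code.

## Robustness battery

The shrinkage simulation redraws per-species multiplicative factors from a
log-uniform distribution on the configured range (the distribution's shape
is an interpretation — the sources state only the range — so plain-uniform
is available by config), multiplies either one compartment per species
(within-brain mode: differential shrinkage between compartments; which
compartment carries the factor only mirrors the intercept) or all
compartments by a shared draw (across-brain), refits the PGLS per replicate,
and summarizes slopes (2.5/50/97.5% quantiles) and isometry-call fractions.
Factors are drawn per species, not one per dataset: a single global factor
adds a constant in log space and cancels exactly in the regression.
The analysis-scale default is 10,000 replicates; tests use 25–300 with
correspondingly widened statistical tolerances.  Reports are bit-identical
for identical seed and config.

Subset comparisons summarize the specimen subsets to species medians, refit
PGLS inside and outside, and test the species-level grouping (species
assigned by majority of specimens, ties inside) by pANCOVA.  The literature
filter excludes observations differing from a per-species reference volume
by more than a factor (default 2.0, boundary retained) and logs every
exclusion with both values; the log round-trips against the original table.

## Synthetic data

The generators' defaults are the study conditions: 34 tips, tree rescaled to
a 73-my root, allometry a = −0.58, b = 1.0, root log₁₀ predictor 4.0 (the
scale of the reconstructed ancestral cerebrum), BM rates σ²_x = 0.01 and
σ²_e = 2e−4 per my — giving a cross-species spread of log-volumes and a
residual scatter of ≈ 0.12 log₁₀ units at the tips, matching the observed
regressions — and intraspecific MAD% of 10 (within the observed 5–20% band).
The residual e is BM on the same tree (phylogenetically structured), which
is exactly the model under which PGLS is the right estimator; an iid mode is
available to demonstrate PGLS/OLS divergence.

Trees are pure-birth: from two lineages at the root, each k-lineage interval
is Exp(k·b) and ends with a uniformly chosen split, with a final
Exp(n·b) interval to the present, so E[root age] = Σ_{k=2..n} 1/(k·b) — the
closed form the tests check.  Intraspecific noise is lognormal (volumes are
positive and are analyzed in logs): specimen = median · e^{sZ}, with s
solving Φ(ln(1+q)/s) − Φ(ln(1−q)/s) = ½ for the target population MAD
fraction q, found numerically by bisection.  Sample MAD% at small n is
biased low relative to the population target; calibration checks use large
n.  Every generator requires an explicit seed.

The bundled species-median table is a literal constant (provenance described
in its header), never regenerated.  The bundled chronogram is a synthetic
stand-in assembled once from approximate literature divergence dates (root
73 my); it is not the 10kTrees consensus tree, which users must obtain
themselves.  Consequences observed at the stated tolerances: the
cerebello-cerebral slopes, the ansiform-on-cerebrum slope, the ACE root
volume, the isometry call for cerebellum~cerebrum, and all grade-shift
p-values reproduce the published analysis on the stand-in; the
ansiform-on-rest-of-cerebellum slope and intercept land slightly outside the
reproduction bands, and the 13-species ansiform slope CIs are wide enough on
the stand-in that the published hyper-allometry calls are not significant
here.  Those components are genuinely sensitive to the chronogram version.

## What passing tests do and do not show

The synthetic generator emulates the statistical structure the estimators
assume (BM drift, log-log allometric coupling, lognormal intraspecific
noise, occasional grade shifts).  It does not emulate segmentation error,
damaged or deformed specimens, sex/age structure, or systematic
scanner/provenance effects; passing calibration tests therefore shows the
estimators are correct and well-sized under the assumed model, not that the
model is adequate for any particular real dataset.  With phylogenetically
structured residuals a clade indicator is partly confounded with drift, so
grade-shift power at realistic noise is moderate (~0.7 for a +0.3 log-unit
shift at n = 34), and single-seed power/coverage numbers carry Monte-Carlo
error of a few percent at the replicate counts used.

## Numerical conventions

Covariance solves use Cholesky factorization; non-PD proposals are rejected
inside the optimizer.  Designs with condition number > 1e12 (e.g. a constant
predictor) are an explicit error; an ill-conditioned `C` triggers a warning
with the condition number.  Display rounding is half away from zero, 2
decimals for ratios; all internal arithmetic is double precision and
unrounded.  Back-transform is mm³ = 10^log-value, applied only at I/O.
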