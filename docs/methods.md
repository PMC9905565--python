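# Methods

This note documents the models, conventions and numerical choices behind
`springtail_metrics`, what the synthetic-data generator does and does not
emulate, and the problem sizes used by the test suite and the acceptance
script.

## From body length to metabolism

Dry mass is predicted per morphogroup from body length with log–log
regressions, log₁₀ *m*[µg] = intercept + slope · log₁₀ *L*[mm]. Where a
morphogroup carries several regressions, each is evaluated and
back-transformed and the masses are averaged arithmetically (not on the
log scale), so one regression per specimen never dominates through the
transform. The packaged coefficient table
(`data/allometry_synthetic.tsv`) is **synthetic**: the values have
realistic magnitudes for Collembola (a 1 mm animal weighs ~4–7 µg dry)
but are placeholders; measured regression tables with the same columns
drop in directly.

Fresh mass is dry mass times a group conversion factor (> 1 by
validation; ~3.3 corresponds to 70 % body water). Individual metabolic
rate uses the Boltzmann–Arrhenius mass-scaling form for insects,
ln I = 21.972 + 0.759 ln M − 0.657/(kT), with M in **mg fresh mass** and
I in J h⁻¹. The mass unit matters: with grams the predicted site-mean
rates fall two-plus orders of magnitude below the plausible
0.028–2.4 mJ h⁻¹ band for soil springtails, which is asserted in the
tests as a unit-sanity gate (the band describes the bulk of sites, not a
hard envelope — very cold synthetic sites can sit slightly below it).
Temperature is mean annual topsoil temperature, converted as
T[K] = °C + 273.15.

### Coefficient uncertainty (min / mean / max)

Uncertainty in the allometric and conversion coefficients is propagated
by recomputing everything with every coefficient shifted by ± one
standard error. A subtlety: for lengths below 1 mm (log₁₀ L < 0) a +SE
shift of the slope *decreases* the predicted mass, so naively shifting
all coefficients upward does not bound the prediction. The variants
therefore shift each coefficient in the direction that bounds the
log-linear predictor (interval arithmetic), which preserves the intended
ordering min ≤ mean ≤ max for every length. For lengths ≥ 1 mm this is
identical to shifting all coefficients by +SE/−SE. The metabolic-equation
constants themselves carry no SEs and are held fixed across variants.

## Site-level aggregation

* density: per-sample total individuals / sampling area, averaged over
  samples (all samples count, including empty ones);
* biomass and community metabolism: per-sample sums of specimen masses /
  rates per m², averaged over samples; specimens without genus-level
  identification (or without trait data) are excluded from mass-based
  metrics but still count for density;
* mean body mass and mean individual metabolism: community-weighted
  (specimen-abundance-weighted) means per sample, then a symmetric
  10 %-trimmed mean across a site's samples. Trimming drops
  ⌊n·trim⌋ values from each tail (nothing is dropped when n < 1/trim);
  ties are handled by a stable sort. A config switch
  (`trim_level="specimen"`) pools specimens across samples and trims at
  the specimen level instead; the per-sample convention is the default
  because samples are the replication unit of the surveys.

An empty result is an error, never a zero: a site with no mass data
reports its metrics as absent-with-reason.

## Richness

Sample-based rarefaction is the exact hypergeometric expectation
E[S(t)] = Σᵢ [1 − C(m−mᵢ, t)/C(m, t)]; the tests verify it against
exhaustive subset enumeration for all m ≤ 8. Richness extrapolation uses
the incidence-based Chao estimator with the (m−1)/m small-sample
correction in its bias-corrected form Q₁(Q₁−1)/(2(Q₂+1)), which needs no
special case at Q₂ = 0; the classic Q₁²/(2Q₂) form and abundance-based
Chao1 are available but not default. Sites with fewer than three samples
(or no individuals) never receive an extrapolation.

Completeness (observed/extrapolated richness) is modelled as a binomial
GLM with logit link on the continuous proportions,
`completeness ~ n_samples * latitude`, fitted on sites with ≥ 5 samples,
each site with weight 1. Per-term chi-squares are sequential (Type I)
likelihood-ratio statistics from nested refits, matching R's
`anova.glm(test="Chisq")`. Because the proportion variance is modelled
as p(1−p) per unit weight, the standard errors are conservative relative
to the true binomial-denominator variance; the parameter-recovery test
reflects that (coverage well above nominal). Pooled-list sites get
extrapolated richness S_obs / predicted completeness; predictions with
completeness < 0.1 are flagged as extreme.

## Quality filters

The three protocol rules (woodland single-layer, scrub ground-cover
only, shallow soil-only temperate agriculture) are applied independently
and their union excluded, so the outcome is order-independent by
construction. The low-density rule flags sites in the lowest decile of
their ecosystem type that also fall below one third of the type's 1st
percentile; percentiles use linear-interpolation (type-7) quantiles on
the raw scale, and types with fewer than 20 sites are skipped with a
warning. Flagging and exclusion are separate: flagged sites are removed
only via an explicit deny list, mirroring a manual review step while
keeping it reproducible.

## Gradients

Latitudinal belts are 5° wide with edges at multiples of 5, half-open
[lo, hi). Belt averages use the same symmetric 10 % trim and are taken
on the log₁₀ scale for skewed metrics (a trimmed geometric mean); zero
or negative values are rejected with an explicit error rather than
silently dropped, so empty-core sites must be filtered deliberately.
Ecosystem summaries report median and quartiles on the raw scale for the
nine well-represented climate-band × habitat types. The quadratic
latitudinal smoother is an ordinary degree-2 OLS fit to belt means, used
for trend description and figures only.

## Grid extrapolation

The ensemble trains 18 configurations (variables per split 2–7 × minimum
leaf population 3–5) of a pluggable regression engine (random forest by
default, a linear engine for fast harnesses), ranks them by **mean**
10-fold CV R² (folds random but seed-determined), and averages the top
10 refit on all sites. Responses are modelled on the log₁₀ scale and
back-transformed as 10^pred without a smearing correction — a small
known low bias (≈ +1–2 % on the synthetic globe's totals via Jensen's
inequality acting the other way on totals); a smearing flag is left to
future work since the bias is well inside the bootstrap CI width.

The interpolation/extrapolation mask standardizes the training
covariates, keeps the first principal components explaining ≥ 90 % of
variance (minimum 2; on the package's synthetic covariates this is far
fewer than the 11 axes typical of a full 22-covariate stack), builds a
convex hull for every pair of retained axes, and masks pixels falling
outside more than 90 % of the hulls. Hull membership is closed
(boundary counts as inside) and evaluated via the hull facet equations
with a 10⁻⁹ tolerance; degenerate (collinear) pairs are skipped with a
warning.

Uncertainty comes from a spatially stratified bootstrap: 100 resamples
of the sites, with per-region draw counts multinomial in proportion to
the relative land area of four continental regions, each resample
refitted and mapped; the stack is reduced to mean, SD, 2.5/97.5 %
empirical CI and CV layers. Global totals are Σ value × pixel area over
unmasked pixels, with spherical lat/lon cell areas (R = 6 371 000 m);
community metabolism converts to carbon at 730.5 h month⁻¹ via
1 kg fresh = 7 × 10⁶ J, 70 % water, 45 % C of dry matter. Moran's I uses
binary great-circle distance-band weights.

## The synthetic-data generator

Defaults encode the study conditions the pipeline is designed for:
log₁₀ density = 3.7 + 0.02·|lat| + N(0, 0.5) individuals m⁻² (≈ 5 × 10³
at the equator to ≈ 1.3 × 10⁵ at 70°, a ~25-fold latitudinal contrast,
spanning several orders of magnitude across sites); soil temperature
falls linearly from 27 °C at the equator to −10 °C at 70° (± 1 °C
noise); 1 + Poisson(5) samples per site (median 6, capped at 20) of
0.002 m² cores; per-species counts negative-binomial (dispersion 2)
around expected density × area × relative abundance, with lognormal
(σ = 1) relative abundances over a site pool of ~20 species drawn from
a 320-species global pool built on real genus names (so harmonization
tests exercise the packaged checklist); genus body lengths lognormal
(median 0.8 mm, σ_log 0.45) clipped to 0.2–5 mm; habitat mixtures
conditional on climate band (tundra appears as polar scrub/grassland).
These choices make the two headline patterns emerge from the model
rather than being painted on: the ~16–20-fold polar:tropical biomass
trend ratio, and near-flat community metabolism (trend fold ≈ 1.5)
because the Arrhenius temperature factor (~36× between 27 °C and −10 °C)
compensates the density gradient.

What the generator does **not** emulate: real taxonomic composition and
its latitudinal turnover, within-genus body-size gradients, spatial
clustering of sites beyond coarse region labels, seasonal sampling
effects, and method heterogeneity. Passing tests therefore demonstrate
the correctness and statistical behaviour of the pipeline's machinery on
structurally realistic data — not the field accuracy of any particular
global estimate.

## Problem sizes and determinism

Every stochastic component takes an explicit seed; generation is
bit-reproducible given config + seed. The test suite and
`scripts/acceptance.py` use desk-scale sizes chosen to keep the full
pattern visible: 300-site datasets for shared fixtures, a 1000-site
dataset for the latitudinal-pattern checks, 300-pixel synthetic globes
with 150 training sites and 100 bootstrap resamples (the bootstrap
coverage experiment repeats this 50–100 times with a linear engine,
whose speed makes thousands of refits practical; the ensemble logic is
engine-agnostic and is exercised with random forests elsewhere in the
suite). The headline-pattern fold ratios are measured on the quadratic
belt-trend (the same smoother used for figures) rather than on raw
single-belt extremes, which at these sample sizes are dominated by the
1–2 emptiest belts.

## Known limitations

* The packaged allometry table is a synthetic stand-in; conclusions
  about absolute masses require measured coefficients.
* Percentile-bootstrap CIs on grid totals show mild undercoverage
  (~90–93 % empirically at these sizes), inherent to the percentile
  method at moderate n.
* The completeness GLM treats proportions with unit weights; with known
  per-site extrapolation denominators a weighted fit would be sharper.
* Back-transformation of log-scale predictions omits smearing (see
  above).
* The low-density outlier rule is scale-dependent through the quantile
  definition; the quantile method is configurable and documented.
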