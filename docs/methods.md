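# Methods

## Problem and model

`thalmap` estimates continuous allele-frequency surfaces for the three major
forms of alpha-thalassaemia — the double-gene deletion (alpha0, allele
frequency *p*), the single-gene deletion (alpha+, *q*) and non-deletional
mutations (alphaND, *r*) — from point-located population surveys, and converts
those surfaces into expected annual counts of newborns with the three severe
phenotypes: Hb Bart's hydrops fetalis (--/--), deletional HbH disease (-a/--)
and non-deletional HbH disease (aa_ND/--).

### Observation model and transform

A survey of *n* individuals contributes *x* alpha-thalassaemia chromosomes out
of 2*n*. Counts are transformed through the empirical logit

    z = log((x + 1/2) / (2n − x + 1/2)),  v = 1/(x + 1/2) + 1/(2n − x + 1/2),

which is finite at the boundaries and approximately Gaussian with known
per-site variance *v*. *v* enters the model as heteroscedastic observation
noise, so large surveys constrain the field more than small ones.

### Latent field

The logit-scale frequency field of each form is modelled independently as a
stationary Gaussian process with constant mean μ and Matérn covariance

    C(d) = σ² · 2^(1−ν)/Γ(ν) · (√(2ν) d/ρ)^ν K_ν(√(2ν) d/ρ),

plus a non-spatial nugget τ². Distances *d* are great-circle kilometres
(haversine); at the latitudes involved, planar degrees would be noticeably
anisotropic. The default smoothness is ν = 1, the Matérn smoothness implied by
the common SPDE choice α = 2 in two dimensions; ν = 1/2 recovers the
exponential covariance.

Hyperparameters (σ², ρ, τ²; μ profiled out by GLS) are estimated by maximising
the Gaussian log marginal likelihood with multi-start L-BFGS-B on the log
scale (empirical Bayes). Prediction and conditional simulation are exact
Gaussian conditioning given the fitted hyperparameters. This replaces a fully
Bayesian SPDE/INLA-style fit with the same model family; the one substantive
difference is that **hyperparameter uncertainty is not propagated** into the
posterior ensemble, which understates total uncertainty somewhat. The
calibration tests quantify the practical effect: averaged 95%-interval
coverage of known synthetic truths sits near 0.93–0.94 rather than 0.95.

Default hyperparameter search bounds: σ² ∈ [1e−8, 100] (logit scale),
ρ ∈ [5, 5000] km, τ² ∈ [1e−10, 10]; 4 restarts. Surveys at identical
coordinates are merged by pooling chromosomes before transformation, which
both reflects the sampling model and keeps the covariance non-singular.

### Posterior ensemble and summaries

Uncertainty is carried by K (default 100) joint conditional simulations of
the latent field on the prediction grid, inverse-logit transformed to the
probability scale. Posterior-predictive means and credible bands are computed
across realisations **on the probability scale**; quantiles use linear
interpolation between order statistics. Point predictions at arbitrary
coordinates use deterministic Gauss–Hermite quadrature of E[expit(Z)] under
the latent Gaussian posterior, which equals the large-K ensemble mean.

For grids above 4000 unmasked cells, conditional simulation proceeds in
chunks, each conditioned on the full training set; within-chunk joint
structure is exact, across-chunk correlation is dropped. Province-level
burden totals aggregate many cells, so this mainly matters for fine-grained
map artefacts, not for the reported totals.

### Cross-validation

`kfold_cv` uses a seeded random k-way partition (default k = 10), refits the
model on each training remainder and compares held-out observed frequencies
with predicted posterior-mean frequencies: per-fold MAE on the probability
scale and Pearson correlation, then averages. Folds with fewer than two
points (or zero variance) have undefined correlation; these are recorded as
missing and excluded from the average with a warning.

## Genotype arithmetic and burden

With *s* = 1 − p − q − r the wild-type frequency, random mating gives the
four-allele Hardy–Weinberg expansion

    p² + 2pq + 2pr + 2ps + q² + 2qr + 2qs + r² + 2rs + s² = 1.

(The 2ps heterozygote — a silent carrier genotype — is sometimes dropped from
printed nine-term versions of this identity; `hwe_expansion` includes it so
the ten classes sum to one exactly.)

Severe-genotype frequencies with a population coefficient of consanguinity
F ∈ [0, 1]:

| genotype | disorder | frequency |
|---|---|---|
| --/-- | Hb Bart's hydrops fetalis | p² + F·p·(1−p) |
| -a/-- | deletional HbH disease | 2pq·(1−F) |
| aa_ND/-- | non-deletional HbH disease | 2pr·(1−F) |

F defaults to 0 (reliable subnational consanguinity data are lacking); the
exact (1−F) scaling of the HbH terms is asserted in tests and logged by the
pipeline as a consistency check. Note that an F = 0.1 run therefore reports
HbH totals exactly 0.9 times the F = 0 totals — a published comparison that
implies a different ratio cannot be reproduced from these formulas.

Births per cell per year are population × crude birth rate (CBR, births per
person per year; a per-1000 input is accepted behind an explicit flag and
divided by 1000). For each realisation k, the three forms' k-th realisations
are paired (independent posteriors, aligned indices — cross-form posterior
correlation is not modelled), per-cell genotype frequencies are multiplied by
per-cell births and summed within provinces. Cells where a draw gives
p + q + r > 1 are renormalised onto the simplex and counted in a diagnostics
field. Province/national means are means over the K realisation totals;
credible intervals are empirical (1±level)/2 quantiles of those totals, so
province quantiles do not (and need not) sum to national quantiles, while
means are exactly additive. Per-cell births stay real-valued; rounding is a
presentation choice only.

## Synthetic studies

The generator produces data with exactly the structure the model assumes,
which is what makes the calibration tests meaningful and is also their main
limitation: passing them shows the estimator is correct and well calibrated
*under the model*, not that real surveys (non-uniform site placement,
ethnicity structure, geocoding error, diagnostic sensitivity) satisfy it.

* **Truth surfaces** — logit-scale Matérn Gaussian random fields, dense
  Cholesky up to 10⁴ cells (with 1e−10 diagonal jitter), a random-Fourier-
  feature spectral sampler beyond that. Default per-form means/variances are
  chosen so observed maxima sit near the regional scales reported for
  Southeast Asia: alpha0 up to ~5%, alpha+ up to ~26%, alphaND up to ~16%.
* **Surveys** — sites uniform over unmasked cells; sample sizes lognormal
  with mean ~1261 individuals, clipped to [10, 50 000] (tens to tens of
  thousands); allele counts Binomial(2n, truth). Each synthetic survey
  reports all three forms at shared sites.
* **Population** — cell weights exp(c·G) for a unit Matérn field G,
  normalised to a requested total (default 7×10⁷ persons); c = 0 is exactly
  uniform. Default CBR 0.0105 (10.5 per 1000).
* **Provinces** — nearest-seed (Voronoi) partition of the unmasked grid into
  k (default 12) contiguous units, dissolved to shapely polygons.

All generators are pure functions of spec + seed; `simulate_study` derives
per-component substreams from one master seed.

## Numerical and design choices

* Test and example grids are coarse (0.25–1°); production resolution is a
  config choice. The acceptance script uses a 12×12 grid of 0.5° cells,
  90 survey sites and K = 100.
* Rasters are serialised as ESRI ASCII grid text with NaN → NODATA (−9999);
  masked cells always carry NaN internally, never 0. Vector outputs are
  GeoJSON. Everything stays in WGS84.
* Degenerate inputs: a constant field drives σ̂² to its lower bound with μ̂ at
  the common value; x = 0 and x = 2n are handled by the ½-offsets; ties in
  quantiles follow linear interpolation; covariance factorisations that fail
  after jitter raise with the smallest eigenvalue.
* Neighbouring-country surveys inform the fit; predictions are reported only
  within the target mask (border-effect control).

## Known limitations

* No covariates: geographic location is the only predictor.
* Plug-in hyperparameters (see coverage note above); no cross-form posterior
  correlation; chunked simulation drops long-range correlation on very large
  grids.
* The synthetic default of uniformly placed survey sites is more favourable
  than real, spatially clustered evidence bases; a preferential-sampling
  weight surface can be passed to `sample_surveys` but is not the default.
* Burden totals are expected births with the severe genotypes; they are not
  adjusted for differential fetal survival, compound disorders with
  beta-globin variants, or prevention programmes.
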