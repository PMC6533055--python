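# thalmap

Geostatistical mapping of alpha-thalassaemia allele frequencies and estimation
of the newborn burden of its severe forms.

## The problem

Severe alpha-thalassaemia — Hb Bart's hydrops fetalis (genotype `--/--`,
almost always fatal perinatally) and HbH disease (`-a/--` deletional,
`aa_ND/--` non-deletional) — is a major public-health concern in Southeast
Asia. Planning screening and care needs *subnational* estimates of how many
affected newborns to expect, but the evidence base is a scatter of
point-located population surveys reporting allele frequencies for the three
underlying forms: alpha0 (double-gene deletion, allele frequency *p*), alpha+
(single-gene deletion, *q*) and non-deletional mutations (*r*).

`thalmap` is for epidemiologists and health planners who want to go from such
survey tables to continuous frequency maps with uncertainty, and from maps to
province-level expected affected-birth counts with credible intervals.

## The model

Survey counts *x* out of 2*n* chromosomes are transformed through the
empirical logit, z = log((x+1/2)/(2n−x+1/2)) with known variance
v = 1/(x+1/2) + 1/(2n−x+1/2), and modelled as a Gaussian process on the logit
scale with constant mean μ, Matérn covariance (variance σ², range ρ in km,
smoothness ν = 1) and nugget τ², estimated by empirical Bayes (maximum
marginal likelihood). Uncertainty is propagated by K conditional simulations
of the latent field, inverse-logit mapped to frequency surfaces.

Genotype frequencies follow four-allele Hardy–Weinberg proportions with
s = 1 − p − q − r and an optional coefficient of consanguinity F:

    hydrops  = p² + F·p·(1−p)
    HbH(del) = 2pq·(1−F)
    HbH(non-del) = 2pr·(1−F)

multiplied per cell by births (population × crude birth rate) and aggregated
within admin units per realisation; credible intervals are empirical
quantiles over the K realisation totals. See `docs/methods.md` for details
and limitations.

## Worked example

A fully synthetic study (the generator is part of the package) on a 12×12
grid of 0.5° cells: 90 surveys of the three forms, a 70-million-person
population raster, 12 provinces, crude birth rate 10.5/1000.

```python
import numpy as np
from thalmap import AlleleFrequencyGP, GPModelSpec
from thalmap.grids import rectangular_grid
from thalmap.synthetic import simulate_study
from thalmap.geostat import ppd_summary
from thalmap.burden import BurdenConfig, DemographySpec, affected_births, birth_surface

grid = rectangular_grid(west=98.0, south=8.0, cell_size=0.5, n_rows=12, n_cols=12)
study = simulate_study(grid, n_sites=90, total_population=7e7,
                       n_provinces=12, crude_birth_rate=0.0105, seed=42)

model = AlleleFrequencyGP.from_database(study.surveys, "a0", GPModelSpec(seed=42))
result = model.fit()
print(result.summary())

ens = {}
for form in ("a0", "aplus", "and"):
    m = AlleleFrequencyGP.from_database(study.surveys, form, GPModelSpec(seed=42))
    ens[form] = m.fit().conditional_simulate(grid, K=100, seed=42)

mean, lo, hi, width = ppd_summary(ens["a0"], 0.95)
print(f"alpha0 predicted frequency: {np.nanmean(mean.values):.4f} "
      f"(cellwise 95% CI width up to {np.nanmax(width.values):.4f})")

births = birth_surface(DemographySpec(study.population, study.crude_birth_rate))
table = affected_births(ens["a0"], ens["aplus"], ens["and"],
                        births, study.provinces, BurdenConfig(F=0.0))
print(table.national()[["disorder", "mean", "ci_lower", "ci_upper"]].to_string(index=False))
```

Output:

```
Allele-frequency Gaussian process (empirical logit, Matern covariance)
======================================================================
sites (after duplicate merging): 90
smoothness nu:        1
mean mu (logit):      -3.7991
variance sigma2:       0.0790
range rho (km):        101.6
nugget tau2:           1e-10
log marginal lik.:    -24.181
failed restarts:      0
alpha0 predicted frequency: 0.0227 (cellwise 95% CI width up to 0.0218)
                  disorder        mean    ci_lower    ci_upper
 Hb Bart's hydrops fetalis  447.523667  394.532517  487.824709
    Deletional HbH disease 5682.444462 5175.019968 6079.375385
Non-deletional HbH disease 1660.872917 1481.711445 1808.296638
```

The fit recovered a logit-scale mean of −3.80 (≈2.2% frequency), a spatial
range of ~100 km and an essentially zero nugget. Nationally, ~448 hydrops
fetalis and ~7,343 HbH births per year are expected under these synthetic
conditions, with 95% credible intervals from the 100 realisations.

The same analysis runs from the shell against CSV/ASCII-grid/GeoJSON inputs
(column dictionary in `docs/column_dictionary.md`):

```bash
thalmap simulate -c config.yaml    # or point paths: at your own survey tables
thalmap map      -c config.yaml
thalmap cv       -c config.yaml
thalmap burden   -c config.yaml
thalmap report   -c config.yaml
```

Every stage writes a manifest with the config hash, master seed and a SHA-256
of each output; a rerun with the same config and seed is bit-identical.

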