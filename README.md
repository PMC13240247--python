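# boreal

Scenario-based impact assessment for boreal woodland caribou
(*Rangifer tarandus caribou*): disturbance-footprint metrics,
coefficient-driven seasonal resource-selection surfaces with cross-range
transferability diagnostics, and a disturbance–demography model with
stochastic population projection. The package is aimed at wildlife
ecologists and impact-assessment practitioners who need to ask, for a
proposed road network or mine footprint inside a caribou range: *how much
of the range becomes disturbed, how does predicted habitat use shift, and
what does the best available demographic model say about population
growth?*

## The models

**Disturbance metrics.** For a range polygon and a scenario's features,
four percentages of range area are computed: anthropogenic features
buffered by 500 m (`pct_anthro`), area burned within the last 40 years,
unbuffered (`pct_fire`), their union (`pct_total`), and fire outside the
buffered footprint (`pct_fire_excl_anthro`). By set algebra
`pct_total = pct_anthro + pct_fire_excl_anthro` exactly, and the
implementation preserves that identity to machine precision.

**Resource-selection surfaces.** A resource-selection function (RSF) is
applied as published coefficients over predictor rasters (moving-window
land-cover proportions, road density in km/km²): η = Σ βᵢxᵢ per cell,
w = exp(η) (or logistic), rescaled by its maximum to a 0–1 relative
probability of use per season. Transferability of one range's
coefficients to another is diagnosed with cell-wise Pearson correlation
and paired values for scatterplots.

**Demography.** Expected rates come from beta regressions on disturbance:
S̄ (adult-female survival, logit link by default) and R̄ (recruitment,
calves per cow; log link, reported per 100 cows), giving the expected
growth rate in the female-only Hatter–Bergerud form

    λ̄ = S̄ (1 + R̄ / 2)

with a 50 % calf sex ratio. Among-population variation is a beta
distribution around each mean, parameterized by (mean μ, precision φ)
with α = μφ, β = (1−μ)φ. A population is a quantile of that
distribution and keeps its quantile as disturbance changes, so
per-population trajectories never cross. Realized growth λ adds
interannual beta variation, binomial demographic stochasticity, and a
ceiling form of density dependence; populations with realized λ < 0.99
are classed as not self-sustaining.

**Synthetic landscapes.** A seeded generator produces autocorrelated
categorical land cover, disc-shaped burns with ages, a range polygon, and
nested road/mine scenarios whose buffered footprints are calibrated by
bisection to requested percent-disturbed levels — so the entire chain
runs and is tested with no external GIS data.

The shipped RSF coefficient tables and demographic coefficients are
**illustrative**: the original published estimates are not redistributed
here. Supply transcribed values via the documented CSV/YAML schemas for
real analyses.

## Worked example

Expected and realized growth under three disturbance scenarios
(anthropogenic 0.41 / 1.11 / 16.91 %, the base, roads-only, and
roads-and-mines levels of a Ring-of-Fire-style development sequence):

```python
from boreal.demography import DisturbanceCovariates, default_model, expected_rates
from boreal.popsim import SimulationOptions, run_ensemble

model = default_model()
scenarios = [
    ("base", DisturbanceCovariates(0.41, 4.17)),
    ("roads_only", DisturbanceCovariates(1.11, 4.12)),
    ("roads_and_mines", DisturbanceCovariates(16.91, 3.69)),
]
for label, cov in scenarios:
    e = expected_rates(model, cov)
    print(f"{label:16s} S_bar={e.S_bar:.3f}  R_bar={e.R_bar*100:.1f}/100  lambda_bar={e.lambda_bar:.3f}")

opts = SimulationOptions(years=20, initial_females=100, seed=42)
for s in run_ensemble(model, scenarios, opts, n_pops=500):
    print(f"{s.scenario:16s} median lambda={s.lambda_quantiles['50']:.3f}  "
          f"P(lambda<0.99)={s.prop_not_self_sustaining:.2f}")
```

prints

```
base             S_bar=0.875  R_bar=29.6/100  lambda_bar=1.004
roads_only       S_bar=0.873  R_bar=29.4/100  lambda_bar=1.001
roads_and_mines  S_bar=0.834  R_bar=24.7/100  lambda_bar=0.937
base             median lambda=1.003  P(lambda<0.99)=0.43
roads_only       median lambda=1.000  P(lambda<0.99)=0.44
roads_and_mines  median lambda=0.933  P(lambda<0.99)=0.79
```

Under the illustrative coefficients, the base scenario is marginally
self-sustaining in expectation (λ̄ ≈ 1.00), while the roads-and-mines
disturbance level pushes expected growth below the 0.99 threshold and
roughly doubles the share of sampled populations classed as not
self-sustaining. The wide spread (43 % of populations below threshold
even at baseline) reflects the large among-population variation encoded
by the beta precisions.

The same chain is available from the shell:

```bash
boreal synth --extent-km 30 --seed 1 --out landscape/
boreal demography --anthro 1.11 --fire-excl 4.12 --n-pops 25 --seed 2 --out demo.csv
boreal run --config config.yaml     # full landscape -> ensemble pipeline
```

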