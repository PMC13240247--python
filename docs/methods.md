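# Methods

## Spatial conventions

All geometry lives in a single projected equal-area coordinate system
with metre units; layers carry a free-form CRS label and combining layers
with different labels is an error. No reprojection is performed — inputs
must be prepared in the analysis CRS. Area statistics are cell counts on
a square grid (default cell edge 250 m, chosen so the standard 500 m
buffer spans at least two cells). A cell belongs to a polygon when its
center falls inside it; it belongs to a line or point feature when its
center lies within half a cell diagonal of the feature. These
rasterization rules are a documented convention: percent-area numbers
from other GIS workflows will differ at the sub-percent level depending
on their own rules and resolution. Buffering is done in vector space
(shapely Minkowski dilation, 16 segments per quadrant) *before*
rasterization, which makes footprints independent of how a road is split
into segments and avoids resolution artifacts. Invalid geometries are
repaired with a zero-width buffer and a logged warning rather than
rejected.

Raster I/O uses the ESRI ASCII grid format and vector I/O uses GeoJSON:
both are plain text, diffable, and carry everything the computations
need (values, grid anchor, feature class, fire year).

## Disturbance metrics

For one range and one scenario: anthropogenic features (roads, mines,
other human footprint) are unioned, buffered by `buffer_width` (default
500 m), and rasterized; fires with age ≤ `fire_horizon` (default 40
years) at the reference year are rasterized unbuffered — only the
anthropogenic footprint receives the buffer. The four percentages
(anthropogenic, fire, union, fire-outside-footprint) are fractions of the
range's valid (non-nodata) cells. Because they are computed from the same
cell masks, the identity `pct_total = pct_anthro + pct_fire_excl_anthro`
holds to machine precision, and `pct_fire_excl_anthro ≤ pct_fire` always.
CSV output rounds to 2 decimals; full precision is kept internally.

## Resource-selection surfaces

Predictors are derived per scenario: for each land-cover class, the
proportion of cells of that class within a circular moving window
(default radius 5 km; window membership by cell-center distance, windows
truncated at the grid edge); road density as total road length within
the window divided by window area (km/km²), with per-cell road lengths
computed by exact vector clipping of road lines to cell footprints.

A coefficient table (range × season) is applied as η = Σ βᵢxᵢ per cell.
The default transform is the exponential RSF form w = exp(η), rescaled
by its maximum over valid cells to [0, 1]; max-rescaling makes the
surface invariant to any constant added to η, so intercepts are
irrelevant under this transform. A logistic transform
(w = expit(η), then max-rescaled) is available for coefficient sets fit
as logistic use–availability regressions; which form a given published
table assumes must be checked against its source. Seasons are labels
only; no date logic is applied. Nodata in any predictor propagates to
the output cell.

Transferability between ranges is summarized by Pearson r over the
intersection of valid cells of two surfaces on the same grid, with the
paired cell values retained (optionally thinned with a fixed seed) for
scatterplots. A zero-variance surface leaves r undefined; it is reported
as NaN with an explicit flag rather than silently dropped.

## Demographic model

Survival and recruitment are beta-regression predictions from the two
disturbance covariates (percent buffered anthropogenic footprint,
percent recent fire outside it, both 0–100). Links default to logit for
survival and log for recruitment, configurable per model file; the
recruitment prediction is divided by `scale` (100 when the coefficients
are calibrated in calves per 100 cows) so internal math is in calves per
cow. Survival predictions outside (0, 1) — possible under identity or
log links — are clamped with a warning; negative recruitment is an
error. The expected growth rate is λ̄ = S̄(1 + R̄/2): a female-only model
with a 50 % calf sex ratio, where each surviving female contributes R̄/2
female calves.

Among-population variation uses the beta distribution parameterized by
mean and precision, α = μφ and β = (1−μ)φ (stated to avoid
shape-parameter ambiguity). A population is a pair of quantiles
(q_S, q_R); its rates at any disturbance level are the beta inverse CDF
at those quantiles around the predicted means. Because the inverse CDF
is monotone in the mean, trajectories of different quantiles over a
disturbance gradient never cross (rank persistence). q_S and q_R are
independent by default — the joint correlation between a population's
survival and recruitment position is not identified by the inputs we
model — with a `shared` flag to force q_S = q_R. Quantile sampling is
stratified by default (one uniform draw in each of n equal-probability
bins, the survival and recruitment stratifications decoupled by a
permutation) so small ensembles still span the distribution; i.i.d.
uniform sampling is available. The recruitment mean doubles as the beta
mean, so it must lie in (0, 1) calves per cow; a model predicting more
than one calf per cow is rejected rather than silently truncated.

The packaged default coefficient set is illustrative, not published
estimates: logit-linear survival from 0.875 at zero disturbance with
slope −0.020 per percentage point (φ_S = 65), log-linear recruitment
from 30 calves per 100 cows with slope −0.011 (φ_R = 18, scale 100).
Magnitudes were chosen once to give a marginally self-sustaining
population at low disturbance and a clearly declining one near 17 %
anthropogenic disturbance, with among-population spread wide enough that
baseline status is genuinely uncertain — the qualitative regime the
national-model literature describes for low-disturbance northern ranges.

## Population simulation

Yearly loop per population: annual rates (S_t, R_t) are beta draws
around the population means with separate interannual precisions
(defaults φ = 500 for survival, 100 for recruitment — interannual noise
is much smaller than among-population spread); survivors are
Binomial(N_t, S_t); recruited females are Binomial(survivors,
min(R_t/2, 1)) — recruitment applies to post-survival females, and the
R_t/2 clamp keeps the binomial well-defined at extreme draws. Density
dependence is a hard ceiling K = c·N₀ (default c = 5); the functional
form of density dependence is not identified by the sources we model, so
the simplest ceiling was chosen. Extinction is absorbing. With
stochasticity off, expectations replace the binomial draws and realized
λ reproduces λ̄ exactly below the ceiling. Defaults: 20-year horizon,
N₀ = 100 adult females. Realized λ is the geometric mean (N_T/N₀)^(1/T),
0 for extinct populations.

Ensembles sample population quantiles once and reuse them for every
scenario, and each population's RNG stream is derived from (seed,
population index) only — scenario contrasts are therefore paired at the
population level, identical covariates yield identical summaries, and
results do not depend on execution order. Summaries report the
2.5/25/50/75/97.5 % quantiles of realized λ, the mean, and the
proportion below the self-sustainability threshold (0.99).

## Synthetic landscapes

Land cover is a Gaussian-smoothed standard-normal field (correlation
length 2 km by default) thresholded at the quantiles matching the target
class proportions — any seed-deterministic patch-producing process would
do; this one is simple and exactly hits proportions up to sampling
granularity. Fires are random disc polygons with ages uniform over the
configured window, added until the rasterized in-range fraction reaches
the target, with the final disc's radius bisected onto the target (to
about 0.1 percentage points). Scenario roads are a wiggly west–east
corridor (plus parallel spurs for long totals) whose central portion is
kept at shorter lengths, so scenario footprints nest by construction;
mines are jittered square claims centred on road vertices. Scenario
intensity (road km, mined fraction) is calibrated by bisection against
the buffered-footprint percentage, tolerance ±0.5 percentage points by
default.

Default study conditions: three nested scenarios at 0.41 / 1.11 /
16.91 % buffered anthropogenic disturbance with a 4.27 % recent-fire
fraction — the base, roads-only and roads-and-mines development levels
the package is designed to contrast.

What the generator does *not* emulate: real land-cover joint structure
(peatland hydrology, succession, fire-landcover interaction), realistic
road network topology, or any collar-data-derived seasonal behaviour.
Passing tests on synthetic fixtures demonstrate that the computational
chain is correct and internally consistent, not that any particular
real range's numbers are reproduced; reproducing published range-level
percentages additionally requires the original GIS layers and matching
rasterization conventions.

## Problem sizes and numerics

The test suite and the acceptance script run on 20–30 km synthetic
ranges at 250 m cells (up to ~200×200 cells), 500-population ensembles,
and 10,000-replicate Monte-Carlo checks; these sizes were chosen to make
the full chain a seconds-scale run while keeping Monte-Carlo standard
errors far below the tolerances tested. Beta inverse CDFs come from
scipy's regularized incomplete beta inversion (verified against brentq
root-finding to 1e-8); exp(η) is computed as exp(η − max η) before
rescaling to avoid overflow; ties in land-cover classification follow
numpy's searchsorted on quantile cut points.

## Known limitations

- No reprojection: all inputs must share one projected equal-area CRS.
- Percent-area metrics depend on the stated cell-center rasterization
  convention and resolution.
- The shipped coefficient sets are illustrative; conclusions about any
  real range require transcribed published coefficients and real GIS
  layers.
- The demographic model is aspatial: disturbance enters only through the
  two range-level covariates, and competing regression forms with
  similar support are not averaged over.
- Recruitment means at or above one calf per cow are outside the
  among-population beta machinery by construction.
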