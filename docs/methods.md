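# Methods

This note documents the models, the numerical choices and the limits of
what the test suite demonstrates. Units are hectares for areas and
t C ha⁻¹ for carbon densities and stocks throughout.

## LULC accounting

The landscape is described by nine CORINE-style categories (agroforestry,
fruit-tree plantations, managed forest, mixed forest, grassland,
unproductive area, non-irrigated arable land, uncultivated productive
area, water body), carried as integer raster codes 1–9 with 0 reserved
for nodata. Three packaged area tables give the hectares per category for
1929 (cadastral survey), 1954 (first national aerial survey) and 2024
(current remote-sensing product) over the Lombardy + Emilia-Romagna study
area.

Transition accounting is cell-wise cross-tabulation of two aligned
categorical grids: `flow(i, j) = cell_area × #{cells i→j}`. Cells that
are nodata in *either* grid are excluded from the pair, which makes the
from- and to-marginals of the transition table equal by construction —
an exact integer-counting invariant, tested without tolerance. Zonal
extraction follows the same categorical semantics: a cell belongs to a
zone by its zone-raster value alone, with no partial-cell area weighting.
This keeps all area totals exactly conserved under any partition, at the
cost of ignoring sub-cell boundary geometry; for the grid resolutions the
accounting is meant for, that error belongs to the upstream
rasterisation, not to the accounting.

Raster I/O handles single-band integer TIFFs via `tifffile`, honouring
the GDAL_NODATA tag (42113) that GIS toolchains use in GeoTIFFs.
Vector geoprocessing, reprojection and cartography are out of scope; the
package consumes ready grids and tables.

## The silvoarable carbon model

The per-hectare stock of the mulberry–vine–wheat system is the pool-wise
sum (InVEST convention: AGC + BGC + DM + SOC) over the three crop
components; additivity is exact and tested as such.

Because the historic system no longer exists, the allometry is
deliberately pluggable with documented defaults rather than fitted:

| constant | default | meaning |
|---|---|---|
| `form_factor` | 0.5 | stem-volume reduction of the DBH cylinder (broadleaf convention) |
| `carbon_fraction` | 0.47 | t C per t dry biomass (IPCC default) |
| `wheat_biomass_multiplier` | 1.0 | standing biomass per unit grain yield |
| `dm_fraction` | 0.0 | dead-matter pool as a share of tree AGC |

The default stem form is cylindrical volume × form factor × wood
density; a power law `AGB = a·DBH^b` is selectable per configuration for
users with species-specific coefficients. The dead-matter pool defaults
to zero because no dead-matter datum exists for the historic system; the
hook is there for managed variants. Compartment soil organic carbon
(SOCt, SOCw, SOCv) is interpreted as per-hectare values summed directly
into the SOC pool — the simpler of the two defensible contracts; a
per-tree interpretation (SOCt scaled by tree density) is available
behind `soc_per_tree` but off by default. The TA input is carried in the
parameter vector for completeness but is inert in the default equations:
no defensible equation exists for it, and an inert input is the honest
encoding of that (its sensitivity indices come out zero, which the tests
assert).

The model is a pure function and broadcasts over NumPy arrays, so a
Monte Carlo or Saltelli design evaluates in a single vectorised call.

## Monte Carlo engine

**Outlier filtering.** Literature samples are cleaned by a
skewness-gated two-regime filter. Near-symmetric samples (|g1| ≤ 1.0,
Fisher–Pearson moment coefficient) use a trimmed-mean tolerance: keep
values within `trimmed_mean(10%) ± 3·σ̂`, where σ̂ is the standard
deviation of the trimmed core (values inside the 10/90% quantiles)
rescaled by the truncated-normal consistency factor (≈1/0.66 at 10%
trim). Using the core sd rather than the full-sample sd is what makes
the band robust — a contaminated sd would inflate the tolerance until it
covers the very outliers it should reject — and the consistency factor
makes the band equal the usual ±3σ on clean Gaussian data (false-positive
rate ≈0.3% instead of ≈7%). Skewed samples use a median tolerance:
`median ± 3·MAD`, with the raw (unscaled) MAD by default and a
`mad_scale` knob for the 1.4826 normal-consistent variant. All constants
(threshold 1.0, k = 3 in both regimes, 10% trim) are conventional
defaults and configurable. The filter refuses to drop more than 40% of a
sample and never returns an empty one; both refusals raise rather than
silently degrade.

**Simulation sizing.** From a pilot run's sd, the realization count for
a target margin of error ε at confidence c is
`n = ⌈(z_{(1+c)/2}·σ/ε)²⌉`, clamped to [10⁴, 10⁶] by default (the
default n without sizing is 10⁵).

**Propagation.** Each of the twelve inputs gets an independent marginal
(uniform, triangular, or empirical resampling; a degenerate uniform
pins a parameter). No dependence structure is imposed — nothing in the
historical sources supports estimating one. Summaries report min, mean,
median, max, sd (n−1 denominator) and an empirical-percentile CI: the
(α/2, 1−α/2) quantiles of the stock distribution itself. This is a
distribution interval, deliberately wider than a standard-error band;
it is what makes the reported CIs commensurate with between-site
variability rather than with simulation precision.

**Surrogate default ranges.** The per-parameter ranges used by
`default_distributions()` are the package's own literature-plausible
reconstruction of the historic system, chosen once and documented here:
mulberry rows at 50–250 trees ha⁻¹ (cadastral sources put row densities
in this band), mature trees 7–11 m tall with 0.20–0.30 m DBH, hardwood
density 0.52–0.68 t m⁻³, root-to-shoot 0.20–0.30; wheat yield
1.20–1.70 t ha⁻¹ (centred on the 1929 cadastral mean of 1.45); vines at
500–700 ha⁻¹ with 8–12 kg standing biomass each; compartment SOC
dominated by the tree rows (SOCt 35–70, SOCw 9–11, SOCv 4–6 t C ha⁻¹);
TA pinned at zero. Under these ranges the simulated stock distribution
is near-symmetric with mean ≈ 83 t C ha⁻¹ and sd ≈ 11.7, and the
sensitivity ranking is SOCt ≻ TD ≻ all others. These ranges are a
surrogate: the per-parameter tests assert engine properties (exactness
against closed forms, determinism, convergence) and the qualitative
dominance pattern, not any particular published per-hectare value.

## Sobol sensitivity analysis

Sampling uses a scrambled Sobol sequence (seeded) in 2k dimensions split
into base matrices A and B, with the radial hybrid matrices AB_i (and
BA_i when second-order indices are requested): N·(k+2) or N·(2k+2) model
evaluations. Estimators are Saltelli-2010 for S1
(`mean(Y_B·(Y_ABi − Y_A))/V`), Jansen for ST
(`mean((Y_A − Y_ABi)²)/(2V)`), and the standard BA/AB cross-product for
S2; V is the variance over A ∪ B. Small negative estimates are sampling
noise and are reported as-is, with clipped [0, 1] convenience columns in
the exported table (clipping tolerance ε = 0.05 documented in the
result). Zero output variance raises instead of returning indices. The
estimators are cross-checked in the tests against closed forms on
additive linear models, a pure-interaction product model, and a
brute-force double-loop variance decomposition on a dense 2-D grid
(agreement within ±0.02 at N = 2¹³–2¹⁴).

## Scenario engine

Per realization, one density per category is drawn uniformly within its
documented range — i.e. perfect spatial correlation within a category
and independence across categories. This is the unique simple sampling
scheme consistent with both the reported scenario means (area-weighted
range midpoints) and the wide reported CIs (≈ ±9 t C ha⁻¹ for 2024): the
uncertainty being propagated is "where in its plausible range does this
category's regional density sit", not per-pixel noise that would average
away over millions of hectares.

The packaged density ranges come from the national greenhouse-gas
inventory for the established categories, from a comparable InVEST-based
case study for the unproductive/uncultivated classes, zero for water
bodies (enforced as an invariant), and — for agroforestry — the 95% CI
of the silvoarable model's own Monte Carlo output. Sampling agroforestry
uniformly over that CI is the default; `af_sample=` switches to
resampling the empirical stock distribution instead (both have the same
midpoint to within 0.25 t C ha⁻¹, so the scenario means are insensitive
to the choice).

Management transforms move area between exactly two categories (arable →
agroforestry for S_AF; fraction × arable → mixed forest for S_F) and
conserve total area exactly — asserted without tolerance. Sequestration
percentages are computed from mean stocks; the suite references
historical epochs to the preceding epoch and management scenarios to the
2024 baseline. Each scenario in a suite gets an independent child seed
spawned from the suite seed, so the full nine-row table is reproducible
from one integer.

Default realization count is 10⁵ per scenario (runtime well under a
second per scenario; Monte Carlo standard error on a scenario mean
≈ 0.014 t C ha⁻¹, an order of magnitude below the 0.01-precision of the
reported table).

## Synthetic data

The grid-pair generator is constructive: each prescribed flow claims its
exact number of cells, positions are shuffled with the seed, and
everything unclaimed is nodata. Cross-tabulating the pair therefore
returns the prescribed table *exactly*, for any valid table — tested over
100 random tables — which makes the generator a true oracle for the
accounting code rather than an approximate fixture. Flows must be
multiples of the cell area; anything else is rejected rather than
rounded.

Literature-style samples are Gaussian around declared truth values with
a declared share of draws replaced by outliers displaced ≥ k MADs from
the median (random sign and excess), with the outlier indices recorded
so filter recall and precision are measurable, not eyeballed. The
range-table generator perturbs the packaged table while preserving
`0 ≤ lower ≤ upper` and the fixed zero water range.

What the synthetic data does not emulate: spatial autocorrelation of
real landscapes, georeferencing, heavy-tailed or multimodal literature
samples, and correlated parameter errors. Tests passing on synthetic
fixtures therefore demonstrate the *accounting and statistical
machinery*, not the realism of any particular historical input.

## Known limitations

* The silvoarable allometry is a documented convention, not a fitted
  model; absolute per-hectare stocks inherit its constants. The
  sensitivity *pattern* (soil carbon dominant, tree density second) is
  robust across the plausible constants; the absolute variance split is
  not.
* Static stocks only: no growth dynamics, no time-stepped accumulation,
  no economic valuation.
* Independence across parameters and across LULC categories is assumed
  throughout; any real covariance (e.g. soil carbon with tree density)
  would widen or narrow the true intervals.
* The nine-category nomenclature is fixed; finer thematic classes must
  be aggregated upstream.
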