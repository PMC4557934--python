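# Methods

## Model

The pipeline estimates standing-stock biomass (SSB) and annual secondary
production of a size-structured fish community from visual belt-transect
counts, then scales the resulting densities by structural surface area to
evaluate decommissioning scenarios for offshore platforms.

Per individual of total length *L* (cm), with von Bertalanffy parameters
*L*∞ (cm) and *K* (1/yr) and weight-at-length *W*(*L*) = *a·L^b* (g):

* **Growth.** The Fabens form predicts the one-year increment
  Δ*L* = (*L*∞ − *L*)(1 − e^(−*K*)) directly from current length, with no
  age or *t*₀ term — appropriate when only lengths are observed.
  Negative increments (binned lengths can exceed *L*∞) are clamped to 0.
* **Mortality and survivorship.** The length-based estimator
  ln *M* = 0.55 − 1.61 ln *L* + 1.44 ln *L*∞ + ln *K* gives an
  instantaneous natural mortality rate; annual survivorship is the
  exponential companion *S* = e^(−*M*). The three constants come from the
  published cross-species estimator, are hard-coded as the default, and
  can be overridden in `RunConfig` for sensitivity analyses.
* **Somatic production.** *P*(*L*) = *S*(*M*(*L*)) · (*W*(*L* + Δ*L*) −
  *W*(*L*)), in g/yr. Production from fish that do not survive the year
  is excluded by construction. *P* = 0 for *L* ≥ *L*∞, and *P* is
  hump-shaped on (0, *L*∞) for *b* > 1: growth in weight accelerates with
  size while survivorship of small fish is poor.
* **Recruitment production.** Individuals observed at or below the
  length reached after one year of Fabens growth from the settlement
  length (default 1 cm) are treated as having settled within the year;
  their full observed standing biomass counts as recruitment production.
  The original recruit definitions live in cited references rather than
  in the source study, so this threshold rule is the documented default
  and the settlement length is prominently configurable.

**Community metrics.** Annual densities per habitat sub-type pool all of
that year's transects — total count over total area (length × 2 m width)
— rather than averaging per-transect ratios, because survey effort is
proportional to structure area. Total production density = somatic +
recruitment. Masses are carried in grams internally and reported in kg.

**Scenario accounting.** Overall platform values per year are Σ over
habitat sub-types of density × structural surface area; complete
platforms use shallow + midwater + base, partially removed platforms
midwater + base. Retention is computed per year and then averaged across
years; because published summary tables are built from across-year means,
the ratio-of-means variant is reported alongside under a separate name.
Shell-mound overall values multiply mound densities by the mound's areal
extent; an unknown extent yields an explicitly unavailable result, never
zero. Two loss-fraction framings are provided because both are used in
practice: mound-only, 100·mound/(partial + mound), and combined,
100·(shallow + mound)/(complete + mound).

**Imputation and proxies.** Habitat-years that could not be surveyed are
filled with the mean of that habitat's available annual values. Habitats
never surveyed on a platform borrow density metrics from designated donor
platforms (defaults follow the study: Holly's base values for A, B,
Hillhouse and Habitat; the mean of the five southern platforms' shallow
values for the four northernmost platforms). Donors contribute densities
only — areas always come from the recipient's own geometry. Unidentified
rockfish counts resolve to Squarespot Rockfish parameters by default, a
deliberately conservative proxy (low per-individual production).

**Geometry.** When only overall dimensions are known, total structural
surface area is allocated to depth strata in proportion to the
truncated-pyramid volume of each slab, V = (h/3)(A₁ + A₂ + √(A₁A₂)),
with cross-section side lengths interpolating linearly in depth (area
quadratic in depth) — platform jackets flare linearly. Strata are
half-open: shallow [0, cut), midwater [cut, seafloor − 2), base the
bottom 2 m. Measured sub-habitat areas, when available (as in the
packaged table), bypass the allocator.

## Parameters

| Parameter | Default | Units | Why |
|---|---|---|---|
| `cut_depth` | 26 | m | U.S. partial-removal depth (navigation clearance) |
| `base_band` | 2 | m | platform-base habitat is the bottom 2 m |
| `transect_width` | 2 | m | belt-transect width of the survey design |
| `interval` | 1 | yr | the model is annual by construction |
| `recruit_settlement_length` | 1 | cm | nominal post-larval settlement size |
| `unidentified_rockfish_proxy` | Squarespot Rockfish | — | most frequently observed species; conservative production |
| Gislason coefficients | (0.55, −1.61, 1.44) | — | published cross-species estimator; overridable |

Life-history parameters (*L*∞, *K*, *a*, *b*, optional length-length
conversion, transient flag) are inputs per taxon, never fitted here.

## Numerical choices

* Length classes enter all formulas at their nominal recorded value
  (5, 10, …, 300 cm), not bin midpoints: lengths were estimated to the
  nearest 5 cm, so the nominal value *is* the estimate.
* *M* is evaluated at the start-of-interval length *L*. Whether the
  original model used *L*, the midpoint, or an integral is not stated in
  the source; start-of-interval is the simplest reading and the one
  implemented (the interval length is switchable via `interval`).
* For vanishingly small *L* the mortality rate overflows a double; it is
  reported as `inf` and survivorship as exactly 0, so production remains
  0 rather than raising.
* Constant-response OLS (zero variance in *y*) returns slope 0, R² 0,
  F 0, p 1 instead of the 0/0 form.
* Stratum allocation conserves total area to better than 1e-9 relative
  (asserted in tests); per-year scenario additivity (complete = partial +
  shallow contribution) is exact floating-point addition of the same
  terms.
* Standard errors over years are textbook sample SEs (SD with *n*−1
  degrees of freedom over √*n*); a single year reports no SE.

## Synthetic data

The generator emulates the survey's structure: multi-platform,
multi-year, per-habitat 5-cm size-class counts on fixed-length belt
transects, with an optional annual settlement pulse added to the 5-cm
class. Counts are drawn as exact expectations (deterministic mode, which
requires integer expected counts and otherwise fails with a suggested
transect length), Poisson, or negative-binomial (Poisson-gamma,
var = m + m²/k) for patchy schooling. A closed-form oracle computes the
densities and overall metrics implied by a spec, so pipeline equality on
deterministic surveys (to 1e-9 relative, observed ~1e-16) and
unbiasedness under Poisson noise (within 3 Monte-Carlo SEs over hundreds
of replicates) are both testable without any external data.

What the generator does *not* emulate: observer detectability and
avoidance behaviour, depth-structured size distributions within a
habitat, school-level spatial correlation between size classes, taxa
drifting between habitat sub-types across years, and inter-annual
recruitment variability beyond the count model's dispersion. Passing
tests therefore demonstrate correctness of the accounting, not realism
of any particular density field.

## Scope and problem sizes

The packaged tables are the published per-habitat *means*; the underlying
annual survey records are an external deposit. Retention computed from
means is an approximation of the per-year-then-average quantity: on
Platform Edith it gives ~18.4% SSB retention against the published 18.7%,
and fleet-average SSB retention lands about 3 points above the published
80% while production retention lands within a point of 86%. Exact
reproduction of the published retention table requires the annual
deposit; the acceptance script documents the mean-based values it
actually computes. The built-in example synthetic survey uses two
platforms, two taxa, up to three years, and 100 m transects; the Poisson
bias check uses 300–500 single-year replicates of one habitat.

## Limitations

* No detectability or visibility correction: densities are taken at face
  value, as in the survey-based design.
* Partial removal removes the shallow *stratum*, not individual fish by
  depth — observations carry habitat labels, not depths.
* Shell-mound loss is the bounding total-loss case; no temporal decay
  model of mounds after removal.
* Proxy-based imputation assumes donor platforms' densities transfer;
  for the northernmost platforms this likely overstates shallow fish
  densities and therefore overstates the impact of partial removal.
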