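# platprod

Standing-stock biomass (SSB) and annual secondary production of the fish
communities living on offshore oil and gas platforms, and what happens to
both under decommissioning.

When a platform is decommissioned it may be removed completely or
"topped" (partial removal: the structure is cut off at 26 m depth and the
deeper jacket left as reef). Deciding between the options requires
knowing how much fish biomass and production the structure supports and
how much of it survives partial removal — including the fate of the
biogenic "shell mounds" of fallen mussel shells that accumulate on the
seafloor around some platforms. This package implements the
size-structured production model used in that assessment for the 16
platforms off the California coast, as a tested, reusable pipeline that
also runs on synthetic surveys with known ground truth.

## The model

Input data are visual belt-transect surveys (2 m wide) that record counts
of each taxon in 5-cm total-length classes per platform, year and habitat
sub-type (*shallow* 0–26 m, *midwater* 26 m to 2 m above the seafloor,
*base* the bottom 2 m, and *shell mound*).

For a fish of total length *L*, with von Bertalanffy parameters
(*L*<sub>∞</sub>, *K*) and weight-at-length *W*(*L*) = *aL*<sup>*b*</sup>:

* growth over one year follows the Fabens increment
  Δ*L* = (*L*<sub>∞</sub> − *L*)(1 − e<sup>−*K*</sup>);
* natural mortality is the length-based rate
  ln *M* = 0.55 − 1.61 ln *L* + 1.44 ln *L*<sub>∞</sub> + ln *K*,
  and annual survivorship is *S* = e<sup>−*M*</sup>;
* per-individual annual somatic production is
  *P*(*L*) = *S*(*M*(*L*)) · [*W*(*L* + Δ*L*) − *W*(*L*)],
  zero at and beyond *L*<sub>∞</sub> and hump-shaped below it.

**Total Production** of a community is the sum of *Somatic Production*
(counts × *P*(*L*), the survivorship-discounted growth of fish present at
survey) and *Recruitment Production* (the standing biomass of individuals
small enough to have settled within the year). Densities (per m² of
structure) are multiplied by the structural surface area of each habitat
sub-type to give overall kg and kg/yr per platform per year, then
averaged. A *complete* platform sums all three sub-types; a *partially
removed* platform only midwater + base; **retention** is the percentage
remaining. Shell-mound metrics are scaled by the mound's areal extent
where it is known, and loss fractions quantify the additional reduction
if a mound disappears after removal.

## Worked example

```python
import platprod as pp

taxon = pp.TaxonParameters("rockfish", L_inf=30.0, K=0.5, weight_a=0.01, weight_b=3.0)
print(f"growth increment at 20 cm: {pp.fabens_increment(20, taxon):.2f} cm")
print(f"natural mortality at 20 cm: {pp.natural_mortality(20, taxon):.3f} /yr")
print(f"annual production at 20 cm: {pp.individual_production(20, taxon):.1f} g/yr")

fit = pp.ols_depth_area(pp.load_platform_geometry())
print(f"area = {fit.slope:.0f} * depth {fit.intercept:+.0f}  (R^2 = {fit.r_squared:.2f})")

metrics = pp.habitat_means_as_metrics()
partial = pp.partial_removal_summary(metrics, pp.load_platform_geometry())
edith = {r.platform_id: r for r in partial}["Edith"]
print(f"Edith: {edith.ssb:.0f} kg retained of SSB -> {edith.retention_ssb:.1f} %")
```

prints

```
growth increment at 20 cm: 3.93 cm
natural mortality at 20 cm: 0.934 /yr
annual production at 20 cm: 22.5 g/yr
area = 532 * depth -14475  (R^2 = 0.93)
Edith: 352 kg retained of SSB -> 18.3 %
```

A 20-cm fish of this rockfish-like taxon grows ~3.9 cm in a year; its
high mortality (39% annual survivorship) discounts that growth to
~22 g of expected new biomass. Across the 16 packaged platforms,
structural surface area rises by ~530 m² per metre of seafloor depth.
Platform Edith — whose fish community is dominated by a shallow-dwelling
damselfish — would keep only ~18% of its standing biomass after partial
removal; most other platforms keep the large majority of theirs.

The `platprod` command exposes the same pipeline on CSV files:
`platprod simulate` writes a synthetic survey + parameter + geometry set,
`platprod metrics` computes habitat–year densities, `platprod scenarios`
the complete/partial/shell-mound tables, and `platprod regress` the
depth–area fit.

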