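# Methods

This note documents the models, numerical choices and known limitations of
the `ldis` toolkit.

## Geometry handling

All stored geometries are WGS84 lon/lat; all lengths and areas are metric.
Two primitives underpin everything:

* **Areas** are computed on the authalic sphere: geodetic latitudes are
  replaced by authalic latitudes (an exactly equal-area mapping of the
  WGS84 ellipsoid onto a sphere of radius ≈ 6371.007 km) and the spherical
  ring-sum formula is applied.  Polygon edges are treated as straight in
  (longitude, sin authalic latitude); for site- and district-scale features
  the induced error is far below 0.1%.
* **Metric operations** (buffering, perimeters, road lengths, compactness)
  run in a per-feature azimuthal-equidistant frame centred on the feature's
  centroid, on a sphere of local Gaussian mean radius √(M·N).  Using the
  Gaussian radius makes the directional scale errors of the sphere model
  cancel to first order in areas; a 100 m point buffer reproduces the
  closed-form disc area within 0.05% at all tested latitudes (the residual
  is polygon discretisation, 128 segments per circle).

Point-only site locations are replaced by a disc of radius
`point_buffer_m` (default 100 m) for all downstream area work; the ring
between a polygon and its `annulus_width_m` (default 500 m) outward
extension serves as the spatial control zone.

**Circularity** is the Polsby–Popper isoperimetric quotient 4πA/P²,
computed in the metric frame: exactly 1 for a disc, π/4 for a square.  The
source material states the perfect-circle cutoff once as 98% and once as
95%; the score-defining section's 0.95 is the default (`circle_frac`),
and the value is configurable.

**Overlap relations.** For an intersecting ordered pair (A, B) with ratios
rA = |A∩B|/|A| and rB = |A∩B|/|B| against the `dup_overlap_frac` = 0.95
threshold (strict `>`, matching "more than 95%"): both above — duplicates,
recorded as *mutual* nesting because the published schema has no separate
duplicate relation (a log line counts them, and the behaviour is
configurable); one above — subset/superset (`nested_in` /
`contains_small_polygon`); neither — plain `intersecting_with`.  Candidate
pairs come from an STRtree; tests assert exact agreement with brute-force
all-pairs classification.  Administrative-area resemblance requires *both*
mutual ratios to exceed `admin_overlap_frac` = 0.98; among several
qualifying regions the one maximising the smaller ratio wins.

Geometry validity is judged on the *reported* geometry (a bare point is a
valid report; a self-intersecting ring is not).  Invalid polygons are
flagged, never repaired, and skipped in the overlap analysis.

## Overlay metrics

Zonal statistics use exact cell/polygon intersection areas, weighted by
cos(latitude) so weights are proportional to true ground area.  A
centre-point membership rule would quantise badly on the sub-km² sites
that dominate real registries, which is why exact weighting is the only
mode offered.  Sites missing a raster entirely yield missing metrics;
partial coverage is computed over the covered part with the coverage ratio
reported.

Road metrics clip the line layer to the site, measure metric length, and
convert length to covered area through a corridor of configurable total
width (`road_corridor_width_m`, default 10 m) so the 10% area rule can be
applied to a length-based layer; the pure density (km per km²) is reported
alongside.

Loss-year windows around a planting year P are pre5 = [P−5, P−1],
pre1 = {P−1}, post5 = [P+1, P+5].  pre1 ⊆ pre5 by construction.  The post
window is truncated at the raster's last covered year with a flag (never
silently), and an empty post window yields a missing value.  Year-only
planting dates are resolved to July 1 for period arithmetic.

Slope uses Horn's 3×3 finite differences with the grid spacing resolved to
metres at each row's latitude.

## The score

The ten indicators binarise the flags and metrics with the threshold
strictness exactly as the rules are phrased: strict `>` for the 10%
infrastructure rules, inclusive `>=` for the 20% land-cover rules.
Permanent water counts toward the other-land-cover rule by default
(`water_counts_as`), since the ten-field schema has no water indicator of
its own.  Missing indicators are excluded from the score and reported via
completeness = evaluated/10; `strict_missing` treats them as fails.  Both
modes are first-class because the original scoring rule for incomplete
inputs is not documented.

## Vegetation indices and panels

NDVI = (NIR−Red)/(NIR+Red) and NDRE = (NIR−RedEdge)/(NIR+RedEdge) are
bounded in [−1, 1] for nonnegative reflectances; degenerate denominators
yield missing values.  SAVI follows the form used throughout this
pipeline's index table — (NIR−RedEdge)/(NIR+RedEdge+L)·(1+L) with L = 0.5 —
which differs from the textbook red-band SAVI; the red-band variant is a
config switch (`savi_uses_red`) rather than a silent correction, and both
L and the gain are exposed.

Annual composites per site × zone × period: scenes whose cloudy share over
the zone footprint is ≥ `cloud_frac_max` = 0.20 (strict `<` keeps) are
dropped; among the remainder the top-`greenest_k` = 3 months by zonal-mean
NDVI are composited (median by default, mean via config), with ties broken
toward earlier months and an optional fixed regional month list bypassing
selection.  Scenes without a cloud mask are retained with a warning.
Panels may be unbalanced; balancing is deferred to the analysis stage.

## Impact analysis

`DiDModel` fits the saturated two-group/two-period regression by OLS
(statsmodels under the hood) and returns a `DiDResults` with estimates,
classical homoskedastic standard errors (matching how the reference
regression table is reported; a cluster-by-site option exists but is off
by default), R², residual SD and the four cell means.  Because the design
is saturated, the coefficients equal cell-mean contrasts — the tests use
this identity as an oracle.  The counterfactual series drops the
interaction: the treated-after prediction intercept+β₁+β₂ is the
no-effect benchmark, and observed minus counterfactual equals β₃.

The one-year-*before* comparison is encoded with t = 0 one year before
planting and t = 1 at planting, which reproduces the positive
pre-planting time term (annuli green up while sites are cleared).

Bootstrap mean-change CIs resample whole sites with replacement (both
zones together, preserving pairing), percentile 2.5/97.5 over `B`
replicates, seeded and bit-reproducible.

The synthetic control assigns randomly sampled control points to
equal-probability quantile buckets of the sites' at-planting NDVI
distribution (default 10 buckets, configurable — the bucket count is not
documented in the source material) and weights each bucket's per-period
control mean by the sites' share in that bucket.  End buckets are open, so
every finite control value is assigned; buckets without control points are
dropped and the weights renormalised with a warning.

## Synthetic data: what it emulates, and what it does not

`gen_sites` fabricates the pathologies the integrity stage must detect:
convex polygons (squashed so compactness stays below 0.90), near-perfect
circles (64-segment discs), exact administrative-area copies, bare points,
plus injected duplicates (99% concentric copies → mutual overlap > 95%)
and nested children (half-linear-scale → 25% of the parent).  Sites are
laid out on a slot grid so no *unintended* overlaps occur, and the
generator records the exact flag vector each site must trigger.

`gen_rasters` paints per-site class fractions cell-by-cell in descending
weight order until the target share is reached, so the generator's truth
and the pipeline's measurement agree within one cell of quantisation.
Sites that share area with another site are left unpainted so every
painted cell belongs to exactly one site.  Road failures are painted as
parallel chords at spacing corridor-width/target-cover.  Default targets
put failing sites clearly past the thresholds (e.g. 30% built against the
10% rule), so quantisation can never flip an indicator.

`gen_reflectance` inverts the NDVI formula with NIR+Red = 1 so painted
cells hit their target index exactly; RedEdge mirrors Red.  The painted
trajectory follows the observed narrative: site at pre-planting level,
clearing dip of `clearing_dip` = 0.10 at planting, linear recovery at
`growth_rate` = 0.02/yr, and the annulus receiving its own baseline plus
`spillover` = 0.3 of the site trend.  Cells on the site boundary are
assigned to the site, so site zonal means are exact and annulus means are
contaminated by at most a boundary-cell sliver (~1–2% of the ring area at
10–30 m resolution).

`gen_did_panel` draws balanced 2×2 panels with iid Gaussian noise; the
four published regression columns are available as named presets
(`one_year_before/after`, `two/five_years_after`) carrying their printed
coefficients, residual SDs and sample sizes.  The before-column's printed
n of 139,250 is not divisible into four equal cells; the preset uses
139,248.

None of this emulates real landscape structure: no spatial autocorrelation
in noise, no seasonality beyond the month-compositing hooks, no mixed
land-cover gradients, no cloud climatology.  Passing tests therefore
demonstrate that the *pipeline machinery* is correct against known ground
truth — not that any particular real-world corpus would score one way or
another.

## Problem sizes and numerical choices

The test suite runs scenarios of 4–50 sites on 10–30 m grids (rasters of a
few hundred cells per side), 200-site overlap tables for index/brute-force
equality, 10,000-site point cohorts for the structural zero-perfect-score
property, and DiD panels at the full published sizes (up to 469,500
observations — OLS on a 4-column design is cheap).  Acceptance-style
coefficient-recovery checks average 8 seeded replicates per column so that
the ±0.003 coefficient and ±0.002 R² bands sit at ≥ 3.5 standard errors of
the averaged estimate.  The closed form R² = var(cell means)/(var + σ²)
agrees with three of the four printed R² values to < 0.001 and with the
one-year-before column to 0.0012 — within the ±0.002 band, the residual
being attributable to rounding of that column's printed inputs.

Tie-breaks: greenest-month ties resolve to the earlier month; equal-best
admin matches resolve to the higher minimum overlap ratio; duplicate site
ids are deterministically suffixed (`__2`, `__3`, …) rather than rejected,
because registry sources are explicitly messy.  Reported values (areas,
dates) are never overwritten by derived ones; both columns coexist.

## Known limitations

* Vector IO covers GeoJSON, CSV-with-WKT and (Geo)Parquet with WKB
  geometry; raster IO covers GeoTIFF and ESRI ASCII grid.  OGR-backed
  container formats (GeoPackage, Shapefile) are not supported.
* Geometry repair, topology-preserving simplification and reprojection
  services beyond what the overlays need are out of scope.
* The DiD machinery is deliberately limited to the two-period, two-zone
  design; event-study and staggered-adoption estimators are non-goals.
* The common-trend assumption behind the DiD design is reported on
  (pre-period trend gaps are visible in the panel) but not formally tested.
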