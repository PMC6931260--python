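# Methods

This note documents the models, the parameter choices and their rationale,
what the synthetic scenes do and do not emulate, and the numerical
conventions used throughout `orchardpheno`.

## Scope and assumptions

The pipeline assumes a *discontinuous* orchard canopy: trees on a regular
planting grid (the defaults are scaled to 6 m along the row × 7 m between
rows), open-vase crowns that do not merge into a closed canopy, ground
visible between rows, and terrain that is locally planar (flat to ~10–15 %
uniform slope). Input clouds come from structure-from-motion photogrammetry
and carry 8- or 16-bit RGB; the reconstruction itself, georeferencing and
flight planning are outside the package (its input is the finished cloud).
Absolute flower counts per tree are not claimed: the detector counts
*flower points* of the cloud, a proxy whose absolute calibration would need
independent field counts. All comparative statements (between trees,
varieties, dates) rely only on that proxy being consistent, which the panel
calibration provides.

## Terrain model

Per-cell (default 2.0 m) ground elevation is estimated in stages:

1. **Provisional surface** — the 5th percentile of *z* per cell. In a 6 × 7 m
   orchard, ground is visible in almost every 2 m cell and the low quantile
   rejects canopy returns. Both cell size and quantile are exposed because
   the appropriate values depend on canopy closure.
2. **Canopy-cell rejection** — cells whose provisional value exceeds the
   5 × 5 grey-opening (minimum-then-maximum filter) of the grid by more than
   `reject_dz` (0.5 m) are discarded. This catches cells lying entirely
   under a dense crown, where even the 5th percentile lands in the canopy.
   The opening preserves a linear slope exactly, so sloped ground is not
   rejected; 0.5 m is safely below the 0.8 m crown-base gap and safely above
   the per-cell relief of a 15 % slope at 2 m cells (0.3 m).
3. **Fill** — rejected/empty cells take the nearest valid cell's value, then
   a single 3 × 3 mean pass smooths only the filled cells (deterministic and
   boundary-safe).
4. **Refinement** — points within `refine_dz` (0.25 m) of the provisional
   surface are accepted as ground; per-cell means replace the provisional
   values, iterated three times so that filled cells converge onto the
   ground points they do contain. A plain low quantile is biased low by
   ~`slope × cell × 0.45` (≈ 9 cm on a 10 % slope at 2 m cells); the
   refinement removes this bias. The band of 0.25 m accepts all ground
   points under realistic noise (cm-level) while excluding the crown base.
5. **Local plane evaluation** — the final cell value is a plane fit
   (z ~ 1 + x + y over the 3 × 3 neighbourhood's accepted ground points)
   evaluated at the cell centre. This corrects partially covered border
   cells, where a mean sits at the points' centroid rather than the cell
   centre. Cells with fewer than 8 neighbourhood ground points or a
   near-singular normal matrix keep the iterative mean. Coordinates are
   shifted to a local origin before accumulating the moment sums, which
   keeps the normal equations well conditioned for UTM-scale coordinates.

Heights above ground interpolate bilinearly between cell centres, clamped
within the half-cell border; points outside the grid's bounding box are an
error rather than an extrapolation.

## Crown delineation

The canopy (points > 0.5 m above ground; below the 0.8 m crown base, so no
crown points are lost) is rasterized to a maximum-height CHM at 0.25 m and
smoothed with a Gaussian (σ = 1 cell). Apexes are plateau-resolved local
maxima — the smallest (row, column) cell of each plateau, then greedy
suppression by descending height with a 3.0 m minimum separation (half the
along-row spacing) — and seed a marker-controlled watershed on the inverted
CHM restricted to canopy-covered cells. Components under 0.5 m² are
discarded. Crown polygons are exact unions of labelled cells, so polygon
membership and raster label lookup agree, including for points on cell
borders. Crown centroids are means of member-point coordinates, which for
near-symmetric crowns estimate the trunk position.

Each date is delineated independently; across dates, crowns are identified
by greedy nearest-centroid matching with a 2 m displacement radius (well
under half the tree spacing, so jittered centroids cannot jump trees).

## Crown metrics

- `max_height`: maximum height above ground among crown points.
- `projected_area`: area of the 2D convex hull of the crown's plan-view
  points.
- `crown_volume`: sum over horizontal slabs of hull area × thickness. Slabs
  are anchored at the crown's lowest point (excluding the trunk gap) and the
  last slab takes the residual thickness, so the stack spans exactly the
  crown's height range. Slabs with fewer than 3 non-collinear points
  contribute zero.
- `length`/`width`: extents along the principal axes of the projected
  points; ties are broken toward the configured row azimuth.

The slab-hull volume estimator has a first-order geometric bias: the hull of
a slab's points approximates the slab's *widest* cross-section, giving a
relative overestimate of about `0.75 t` on an upper half-ellipsoid of unit
vertical semiaxis (t = slab thickness). At the same time the hull of `n`
sampled points underestimates a convex cross-section by O(n^(-2/3)). The
0.05 m default thickness balances the two for photogrammetric densities
(hundreds to thousands of points per m³): the geometric bias stays in the
low percent range while slabs keep enough points for stable hulls. Both the
thickness and the per-slab operator are configuration, since published
descriptions of slicing-based crown volumes rarely pin them down. Crowns
with fewer than 4 points or a degenerate plan-view footprint yield a zeroed
record with a `degenerate` flag rather than an error.

## Flower detection

Brightness is `(r + g + b) / 3`, kept unrounded so threshold comparisons do
not depend on a rounding convention. The classification rule is exactly:
brightness **≥** the reference panel's observed mean brightness, *and*
height above ground **>** 1 m. The inclusive/strict pattern matters at the
boundaries and is tested. The grey panel (reflectance 0.43) is the default
reference — the white panel (0.97) is brighter than most flower colors and
classifies almost nothing, and is retained only for that comparison; the
black panel is read purely as a sanity check on the white ≥ grey ≥ black
brightness ordering. Panels lie on the ground, so the 1 m height floor
excludes their own points from classification implicitly. Panel means use
only near-ground points (< 0.3 m) on the footprint, with at least 10 points
required.

Flower counting is planimetric (point-in-polygon on the crown footprint),
matching how crown limits are defined; a point on a shared crown border is
counted once (first crown in id order). Flower points outside every crown
are reported in a residual bucket rather than dropped silently. Density is
count / volume, undefined (NaN, flagged) for zero-volume crowns.

## Statistics

- **Rankings**: one-way ANOVA, then all-pairs Tukey HSD at α = 0.05 via
  statsmodels (Tukey–Kramer under unequal group sizes). Varieties with
  fewer than two trees are excluded with a warning. The compact letter
  display uses the insert-and-absorb algorithm (own implementation), with
  letters assigned in descending-mean order: groups share a letter exactly
  when they are not significantly different. Tests verify the significance
  decisions against a direct studentized-range computation.
- **Calendar**: per-variety mean density per date; peak = argmax; start/end
  are the first/last dates at ≥ 5 % of peak and the full-bloom window the
  dates at ≥ 50 %. The 5 %/50 % fractions mirror the standard field-scored
  bloom stages (5 % of flowers open = start, 50 % = full bloom), but
  applying them to *density curves* is this package's estimator — field
  protocols observe the stages directly — so both fractions are parameters
  and reported alongside the stages. An all-zero curve is flagged
  "no bloom detected" instead of producing arbitrary dates.
- **Yield regression**: per-variety OLS of grouped yield weight on the mean
  crown volume of the same tree groups (volumes must be pooled exactly as
  the harvests were weighed). R², slope *p* (two-sided t) and significance
  flags at 0.05/0.10 are reported; zero volume variance is flagged
  undefined, constant yields give slope 0 and R² = 0 by convention. A
  pooled across-variety fit is available but reported separately, since
  pooling heterogeneous varieties mixes between- and within-variety
  relations.

## Synthetic scenes

The generator emulates the survey conditions the pipeline targets: a
planar (optionally sloped) ground sheet of uniformly scattered points;
trees on the planting grid with upper-half-ellipsoid crowns over a 0.8 m
trunk gap, filled uniformly with canopy points; flower points on the outer
10 % shell of the crown (photogrammetry sees the canopy envelope), kept
above 1.1 m so every generated flower satisfies the detector's height floor
with margin for DTM error; three 0.45 m panels near the field centre whose
channel values are 255 × reflectance (0.97/0.43/0.05); truncated-normal
colors clipped to [0, 255]; and Gaussian coordinate jitter (2 cm default,
cm-level photogrammetric noise). Defaults: 4 rows × 6 trees, 3 varieties × 8
trees (desk-scale in seconds), 1000 canopy points/m³, 20 ground points/m²,
20 flowers/m³. Greenish canopy (mean brightness ≈ 67) and bright flowers
(≈ 205) bracket the grey panel's 109.7, as almond bloom does in practice.

Randomness comes from per-component generators derived from the scene seed
in a fixed order (ground, trees by id, panels, flowers-by-date), so a
(config, seed) pair is bitwise reproducible and crown geometry is frozen
across the dates of a time series while flowers vary.

What the generator does **not** emulate — and what passing tests therefore
do not establish about field data: structure-from-motion artifacts
(holes, ghost points, occlusion — in particular real clouds have *no*
ground points under dense crowns, which the terrain model's canopy-cell
rejection is designed for, but synthetic cells always contain ground),
directional illumination and BRDF effects beyond a uniform gain, chromatic
variety differences (purple-tinged bloom), wind-blurred crowns, and
leaf-on/leaf-off geometry changes. Exact flower-count recovery in the
noise-free scenes validates the *logic* of the classification chain, not
absolute counting accuracy in the field.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use the default 24-tree
orchard for detection/segmentation checks (10–20 seeds), 6-tree scenes at
reduced density for the 30-seed × 5-date calendar recovery, 2 × 10⁵-point
analytic solids for the volume oracles, and 50 random fixtures (k ≤ 5,
n ≤ 10) for the Tukey oracle — sizes at which each quantity's sampling
noise is far below the tolerance being checked, while a full run stays
around a minute.

## Known limitations

- The watershed delineation is tuned to regular grids with discontinuous
  canopies; merged or strongly overlapping crowns beyond the tested 6 m /
  3.2 m-semiaxis case may over- or under-segment.
- The slicing volume is biased for very sparse crowns (hull deficit) and for
  thick slabs (geometric bias); the default thickness assumes at least a few
  hundred points per m³.
- Cross-date matching is greedy nearest-centroid; it assumes displacement
  (jitter plus georeferencing error) below half the planting spacing.
- The DTM assumes piecewise-planar terrain at the cell scale; terraces or
  ditches narrower than a cell are smoothed over.
- The bloom-stage estimator depends on the flight schedule: stages can only
  resolve to the available dates, and a peak between flights is assigned to
  the nearest flown date.
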