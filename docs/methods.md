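# Methods

## The metrics

Both indexes start from the *border depth* of each cell: the Euclidean
distance from the cell centroid to the nearest point of the lesion
boundary, for cells inside (or exactly on) the boundary. Signed
distances follow the negative-inside convention; the metrics use the
magnitude. Distances are measured to every boundary ring, including
holes, matching JTS/QuPath behaviour.

**Lesion preparation.** The lesion polygon is intersected with the
tissue polygon before anything else. This handles lesions drawn over
the tissue edge: off-section area would otherwise count as acellular
lesion and depress tCPI. All depths, erosions and areas — including the
tCPI denominator — use this clipped lesion, which makes the central and
peripheral areas an exact partition of the total (central + peripheral
= total, an invariant the tests assert at 1e-6 relative). Cells outside
the clipped lesion are excluded from both indexes and reported as an
exclusion count.

**tCPI.** With *m* the median border depth (even counts average the two
middle values), the central region is the inward offset (morphological
erosion) of the clipped lesion by *m*, re-clipped to tissue; the
peripheral region is its complement within the lesion; tCPI =
peripheral area / total area. For any continuous radial density this
equals the fraction of lesion area holding the shallower half of the
cells. If erosion by *m* consumes the whole lesion the central region
is empty and tCPI = 1 — a defined value (flagged with a warning, since
it signals an extreme center-packed or degenerate configuration), never
an error. Ties at the median need no special handling because the index
partitions area, not cells.

**immCPI.** The ratio of the mean border depth of marker-matched cells
to the mean border depth of all in-lesion cells. Marker matching is
substring containment on the classification string by default (robust
to composite classes such as `"CD3: CD8"`); an `exact` mode matches
whole `:`-separated tokens for markers that are prefixes of others
(CD3 vs CD34). A lesion with no marker cells yields NaN plus a warning
rather than 0: a zero would masquerade as extreme peripheral
localization. A mean all-cell depth of exactly 0 (every cell on the
border) is an error, as the ratio is undefined.

**Band profile (baseline).** Fixed-width concentric bands from the
border (inward, outward into the surrounding tissue, or both), with
per-band counts, areas (successive erosion/dilation differences,
clipped to tissue) and densities. Bands are half-open in signed border
distance, so a boundary cell belongs to the first inward band. Cells
beyond the banded range are reported as a remainder count so the band
counts always conserve the in-lesion total.

## Geometry

Regions are shapely 2.x polygons; erosion is a negative buffer with
round joins, which is the true morphological erosion (arcs at reflex
vertices). Join arcs are discretized at 256 segments per quadrant: at
the default resolution, composing two erosions (d₁ then d₂ vs d₁+d₂)
disagreed by up to ~9 × 10⁻⁶ in relative area on strongly concave test
shapes; at 256 the error is below 10⁻⁶, at negligible cost. Overlay
operations occasionally emit lower-dimensional fragments (lines,
points) where boundaries touch; these are dropped, as they carry no
area. An empty region is an explicit, valid value (e.g. a fully eroded
lesion), never an error.

Computation is Cartesian in microns throughout; pixel-unit inputs are
scaled once on load by the µm/px calibration, assumed isotropic. No
assumption is made about the y-axis direction — every metric is
invariant under isometries, which the property tests exercise with
random rigid motions and uniform scalings.

## Input handling choices

* GeoJSON class labels are read from `properties.classification.name`,
  falling back to a plain `properties.classification` string, then
  `properties.name` — QuPath versions differ in which they emit.
* Slightly invalid polygons (hand-drawn self-intersections) are
  repaired via `make_valid`; if repair changes the area by more than
  1%, the feature is rejected with its index named, since the drawing
  is then genuinely ambiguous.
* Cell-table columns are auto-detected from common QuPath headers
  (`Centroid X µm`, `Centroid X px`, `x`, ...); an explicit column map
  always wins. Rows with non-numeric coordinates are dropped and
  counted, not silently ignored.

## Synthetic data

The generator emulates the study conditions the metrics are validated
under: a disk lesion of radius 500 µm sampled as a 64-gon (polygon area
within 0.5% of πR²), 20,000 cells per lesion — enough to hold the tCPI
sampling error near 0.003, an order below the 0.02 test tolerance —
inside a tissue rectangle 20% larger than the lesion's bounding box.
Irregular shapes are harmonic perturbations r(θ) = R(1 + Σ aₖ cos(kθ +
φₖ)) with Σ|aₖ| < 1 (star-convex by construction).

Radial profiles are defined on the normalized radius u = ρ/r(θ) rather
than border depth, so the closed forms below remain exact for irregular
star-convex shapes, not just disks:

* `uniform`: constant density; tCPI → 0.5, mean depth R/3 on a disk.
* `necrotic_core` (fraction q): no cells at u < q; tCPI → (1 − q²)/2
  (0.32 at q = 0.6).
* `center_enriched` (fraction q): cells only at u < q; tCPI → 1 − q²/2.

Markers are assigned either independently of position (probability p —
immCPI → 1), or by position (central disk / peripheral band). For a
marker population of fraction f confined to the central disk of radius
c, the all-cell denominator includes the marker cells themselves, so
the exact expectation is

    immCPI = m / ((1 − f)/3 + f·m),   m = 1 − 2c/3R  (depths in units of R)

which tends to the thin-marker limit 3 − 2c/R as f → 0. The bundled
`marker_central` scenario uses c = R/2 and f = 0.1, hence 2/1.1 ≈ 1.818
(the limit value would be 2.0). Sidecar files always record the exact
mixture form for the parameters actually generated.

Sampling is batched rejection over the bounding box — exact and fast at
this scale (a 20,000-cell lesion generates and scores in well under a
second). One integer seed fans out to fixed sub-streams (shape phases,
cell positions, marker labels), so regenerating one component never
perturbs the others, and fixture files are byte-identical for a fixed
seed. Two-population scenarios draw the second population from a
fixed-offset seed stream.

What the generator does *not* emulate: segmentation error and cell
density inhomogeneity unrelated to border distance, anisotropic pixel
calibrations, multi-lobed lesions with non-star-convex radial laws
(the dumbbell scenario exercises the geometry but has no closed form),
and marker misclassification. Passing tests therefore demonstrate the
correctness of the metric computation and its invariances — not
robustness to upstream detection or annotation error, which the
troubleshooting advice in the field's protocols addresses (draw the
border tight; ensure reliable nuclear segmentation).

## Validation oracles

Tests never check the implementation against itself. Areas are
cross-checked by an independent shoelace implementation and by
Monte-Carlo rejection sampling (agreement within 3 standard errors at
10⁵ samples); tCPI on small polygons is recomputed by a 0.1 µm grid
rasterization oracle whose containment test (matplotlib even-odd path),
distance computation (direct point-segment arithmetic) and area
estimate (cell counting) share nothing with the shapely pipeline,
agreeing within 1%. The closed forms above were verified by brute-force
simulation before being frozen into the tests.

## Problem sizes

The validation suite runs each stochastic check as a mean over 10
replicate seeds at 20,000 cells per lesion (tolerances: ±0.02 on tCPI,
±0.05 on immCPI); the whole suite completes in seconds on one CPU, and
`scripts/acceptance.py` re-derives the headline numbers in a few
seconds.

## Known limitations

* Geodesic (within-tissue) distances are not supported; distance is
  straight-line even where the path crosses off-tissue space.
* Anisotropic pixel calibration is not modeled (a single µm/px factor).
* Cells in overlapping lesion annotations are scored in each lesion,
  with a warning; the one-lesion-at-a-time protocol this mirrors has no
  defined semantics for overlap.
* immCPI for cells outside the lesion is undefined by construction;
  out-of-lesion cells only enter the outward band profile.
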