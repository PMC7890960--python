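# Methods

## Data model and geometry

All grids are indexed (z, y, x); multichannel images are (channel, z, y,
x). A voxel's physical position is its center at `index · step`, with the
origin at the center of voxel (0, 0, 0). Spacing is carried in nanometres
throughout the library (the reference confocal geometry is 70 nm in xy and
210 nm in z); unit conversion happens only at the I/O boundary (TIFF
metadata is conventionally in µm) and in reported measurements (lengths in
µm, areas in µm², volumes in µm³). Label maps are consecutive integers
1..k with 0 as background; components are ordered by decreasing voxel
count, ties by the smallest linear index — a total order that makes every
labeling deterministic.

## Histogram thresholding

Histograms use equal-width bins spanning [min, max] of the selected
voxels, with the rightmost bin closed; integer images whose range fits get
one exact bin per integer value (default cap 65536), so thresholds on
integer data are exact intensities. Thresholds are reported as bin *lower
edges* and the "lower" direction selects values ≥ t — bright nuclear
structures are foreground.

Every automated selector is an exact, exhaustive optimization of its
criterion over cut points; there is no stochastic search:

* **Otsu / multi-level Otsu** maximize between-class variance
  (equivalently Σ_c S_c²/W_c with per-class weighted sums); k-class search
  is exhaustive over cut combinations up to ~4·10⁵ candidates and falls
  back to an O(k·n²) dynamic program for very large histograms. Otsu is
  the k = 2 case of the same search, so the two agree identically.
* **Rényi entropy** maximizes H_α(background) + H_α(foreground) with
  within-class normalized probabilities, H_α = ln(Σ p_i^α)/(1−α); α = 1 is
  evaluated as the Shannon limit (the Kapur maximum-entropy threshold).
  Default α = 2; the three-alpha combination variant found in the
  literature is out of scope.
* **Shanbhag** minimizes |E_back − E_fore|, where each class weights its
  bins by a cumulative fuzzy membership (1 far from the threshold,
  approaching ½ at it): μ_back(i) = 1 − P(<i)/(2·P_back) and symmetrically
  for the foreground.

Tie handling: cut points that differ only across *empty* bins induce the
same partition, so only cuts immediately above an occupied bin are
searched and ties resolve to the lowest qualifying edge (lexicographically
smallest threshold vector for multi-level Otsu). This canonicalization is
what makes exact equality with an independently coded oracle a meaningful
test.

## Fuzzy distance transform and Multiscale Opening

The fuzzy distance transform (FDT) is a shortest-path distance on the
26-adjacency graph restricted to a region. The step cost between adjacent
voxels u, v is ℓ(u,v) · (w(u,v) + ε), where ℓ is the anisotropic
center-to-center Euclidean length, w = (2 − μ_u − μ_v)/2 for object
distances (bright paths cheap) or (μ_u + μ_v)/2 for background distances
(dim paths cheap), and ε = 10⁻⁶ keeps edge costs positive on μ = 1
plateaus so Dijkstra stays well-founded. The graph is assembled
vectorized (13 half-offsets) and solved by a multi-source run of
`scipy.sparse.csgraph.dijkstra`; tests compare it with an independent
heap-based Dijkstra to 10⁻⁹.

Multiscale Opening separates conjoined structures:

1. Envelope E = {I ≥ t_env}; cores = size-filtered components of
   {I ≥ t_core} (t_core > t_env); background seed B = complement of E.
2. μ = clip((I − t_env)/(t_core − t_env), 0, 1).
3. Iterate: object FDTs d_i from each object's current seed set over
   E plus one 26-neighbor layer of background (paths may shortcut just
   outside the envelope); background FDT d_B from B over the whole grid,
   computed once since B never changes. An unlabeled envelope voxel joins
   the nearest object iff min_i d_i < d_B; exact ties between objects
   leave the voxel unlabeled (a deterministic one-voxel separating line).
4. Newly labeled voxels become seeds; repeat until no voxel changes
   (bounded by max_iterations, default 100; the labeled set grows
   monotonically and is bounded by |E|, so termination is guaranteed).

The labeling rule has a consequence worth stating: envelope voxels whose
membership is low and which sit next to the background (e.g. a dim bridge
skin one voxel from outside) are *closer to the background* and stay
unlabeled. That is by design — the rule is what prevents watershed's
forced partitioning — and it means MSO output is a subset of the envelope,
not a partition of it.

Seeded watershed (the comparison method) is classical flooding via
`skimage.segmentation.watershed`: variant "distance" floods the negated
anisotropic EDT to the background, variant "intensity" floods
brightest-first. Seeds keep their identity in both algorithms.

## Measurements

* **Volume** = voxel count × step_z·step_y·step_x.
* **Surface** = exposed-face sum, each face weighted by its physical area
  (grid-boundary faces included). Exact for digital solids; it
  overestimates the area of a smooth surface and no smooth-surface claim
  is made.
* **Diameter** = maximum pairwise (Feret) distance between voxel centers,
  computed on boundary voxels and reduced to convex-hull vertices for
  large components. An equivalent-sphere diameter was the other candidate
  reading; max-pairwise was chosen and is stated here.
* **Moment** = Σ_v m_v·r_v² with m_v the raw channel brightness (no
  background subtraction — any correction must happen upstream) and r_v
  the distance from the brightness-weighted center of mass; units
  intensity·nm².
* **Principal axes**: eigen-decomposition of the brightness-weighted
  covariance of voxel positions about the center of mass; axis i's length
  is the extent (max − min) of voxel-center projections onto eigenvector
  i; eigenvector signs are fixed (largest-magnitude entry positive) for
  determinism.
* **Border rim**: rim = {v ∈ mask : EDT(v) ≤ rim width}, where EDT is the
  exact anisotropic distance to the nearest *outside voxel center*; no
  sub-voxel surface interpolation is attempted. Consequently the one-voxel
  boundary shell sits at distance = one step, a width below the smallest
  step selects nothing, and the digital rim is biased thin by roughly half
  a step — comparisons with analytic shells should use spacing fine
  relative to the rim width (tests use 40 nm for a 300 nm rim on a 1 µm
  ball, where the measured error is ~1.5 %).
* **Distance bands**: radial coordinate from the mask's geometric center
  (border-referenced variants are a recorded extension point, not
  implemented). Equal-radius mode splits [0, r_max] into k equal
  intervals. Equal-volume mode ranks voxels by radius with a stable sort
  and splits at the j/k rank quantiles: on symmetric digital masks many
  voxels share one exact radius, and value-quantile edges cannot split
  such a tied shell (band sizes then drift by >2 %), whereas rank
  splitting is equal-volume by construction and coincides with quantile
  edges when radii are distinct.
* **ROI-to-mask distance**: between the ROI's brightness-weighted or
  geometric center and the mask's geometric center, or the minimum over
  ROI voxels of the distance-to-border field.

Measurement sets are declarative JSON; evaluation emits one row per
component plus a "total" row for aggregates (count, volume ratio to mask,
distance-band contents), with units in the column headers and a
provenance sidecar naming every realized parameter.

## Phantoms

Phantom membership is binary at voxel centers — no partial-volume
anti-aliasing and no PSF simulation; test tolerances absorb digitization
error. The only noise model is additive Gaussian (clipped at zero),
because tests need controlled signal-to-noise rather than photophysical
realism; consequently passing tests demonstrate algorithmic correctness,
not robustness to the structured noise, bleed-through or shading of real
confocal data. Every phantom is a pure function of (parameters, seed).

* *ball / ellipsoid*: analytic membership, optional rigid rotation;
  exercise volume/surface/diameter/moment/principal axes against closed
  forms ((4/3)πR³, (3/5)MR², 4:2:1 axis ratios).
* *bridged blobs*: two balls (default radius 10 voxels) joined by a
  cylindrical bridge at 30 % of blob intensity; truth assigns bridge
  voxels to the nearer blob with the equidistant mid-slab excluded.
* *gradient blobs*: an elongated capsule whose brightness oscillates
  between 140 and 200 with three internal maxima, bridged to a uniform
  ball — the scenario where intensity watershed seeded at local maxima
  oversplits (≥4 labels for truth 2) while two-stage core detection keeps
  the capsule as one core. Maxima positions are exposed in `parameters`.
* *nucleus scene*: non-overlapping spherical nuclei (DNA-like channel at
  intensity 80) containing brighter chromocenter spots (200) and a second
  channel of small bodies (150), with per-nucleus truth counts; spot
  placement enforces a three-step clearance so digitized spots never
  touch.

Default phantom spacing is isotropic 70 nm (measurement-analytics tests
use 100 nm so a 1 µm ball is exactly 10 voxels in radius); the scene
phantom uses the anisotropic confocal reference spacing (210, 70, 70) nm.

## Pipelines and batch

Profiles, pipelines and measurement sets are pydantic models serialized as
JSON with `format_version` "1"; loaders reject unknown algorithm ids and
higher major versions, and serialization round-trips exactly. A pipeline
step may declare that it requires a mask; validation rejects chains where
no earlier step produced one (`use_as_mask`, with optional label selection
and physical-radius dilation). Batch execution is per-file independent —
the only parallelism is across files, so output is a pure function of the
sorted input list and is byte-identical for any worker count; per-file
failures become error-report rows rather than aborting the run, and the
CLI exits non-zero if any occurred.

## Problem sizes and numerical choices

The test suite and acceptance script run in well under a minute on one
CPU: oracle suites use 1000 random 16–32-bin histograms and 200 random
6×6×4 FDT grids; phantom grids are 10⁴–10⁵ voxels. Degenerate inputs are
errors with stable messages ("degenerate histogram", "empty mask",
"threshold order", "no core objects"), not silent defaults. Floating-point
ties in selector criteria are avoided structurally (canonical cut points)
rather than with epsilon comparisons; the FDT/oracle agreement tolerance
is 10⁻⁹ nm on grids whose path lengths are O(10³) nm.

## Known limitations

* MSO's morphological scale selection from the original formulation of
  multiscale opening is not reproduced; the two-threshold membership ramp
  with complementary edge costs and iterative re-seeding is this package's
  concretization of the brightness-and-distance path-cost idea.
* No local/adaptive thresholding, no hierarchical watershed, no
  deep-learning segmentation, no GPU paths.
* Surface area is exposed-face area, not a smooth-surface estimate.
* TIFF support covers pixel-size metadata only (ImageJ convention), not
  full OME-XML.
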