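# Methods

## Problem and model

A predicted target structure is a binary mask on a 3D voxel lattice with
physical spacing (mm). Its *main structure* is the largest connected region;
every other connected region is an *outlier* (random false positive). The
pipeline measures outliers, propagates them through clinical target
construction (CTV = GTV ∪ edema; PTV = CTV grown by an isotropic margin),
fuses multiple models by majority vote, and evaluates dose surrogates.

### Connectivity

Connectivity is not a neutral choice: under 6-connectivity, corner-touching
fragments of one lesion would be counted as separate outliers. The default
is therefore 26-connectivity (faces, edges, corners), configurable to 6
everywhere it matters. All experiment generators guarantee outliers are
disconnected under 26-connectivity (a one-voxel gap in every axis), which
implies disconnection under 6-connectivity as well.

### Component metrics

- *Voxel volume* = voxel count × voxel size (mm³). Exact by definition.
- *Mesh volume* = volume enclosed by the 0.5-level isosurface of the binary
  occupancy field, computed by marching cubes (one-voxel zero padding closes
  the surface; physical spacing applied) and signed-tetrahedron summation
  over the triangulation. For convex digitized blobs the isosurface lies
  inside the voxel hull, so mesh < voxel volume, with the relative gap
  shrinking as the object grows against the voxel size — the qualitative
  behaviour of treatment-planning-system mesh volumes. No attempt is made to
  match any proprietary meshing algorithm numerically; for an axis-aligned
  cube of side a (unit voxels) the implementation reproduces the closed form
  a³ − 1.5(a − 1) − 5/6 exactly (planar faces half a voxel outside the
  boundary centers, straight edge bevels of 1/8 per unit length, corner
  bevels of 5/48).
- *Distance to main* = minimum spacing-aware Euclidean distance between
  voxel centers, computed from the exact Euclidean distance transform of the
  main component. Center-to-center (not surface) distance is used because it
  is exactly testable against a brute-force pairwise minimum.
- Ties for "largest component" are broken by the component whose centroid is
  closest to a reference point (the brain centroid when available), then by
  lowest label. Ties are essentially impossible in realistic masks; the rule
  only pins determinism.

### Margin growth

`expand_margin` includes a voxel iff its center lies within the margin
(Euclidean, spacing-aware) of an occupied voxel center, implemented by
thresholding a Euclidean distance transform. This is exact on anisotropic
grids (e.g. 1 × 1 × 3 mm CT), unlike repeated structuring-element dilation.
Negative margins erode, defined symmetrically on the complement. Note that a
margin smaller than the voxel spacing cannot move a boundary: the ±1 mm
ladder of the relative-size experiment produces strictly nested masks only
on grids of ≤ 1 mm spacing.

The PTV margin default is 3 mm isotropic, the RTOG-style glioblastoma
convention. The PTV is clipped to the body contour when present, never to
the brain — false positives can lie outside brain tissue and must survive
into the PTV inventory. Whether clipping applies at all is configurable.

### Majority voting

Voxelwise vote with threshold floor(n/2) + 1 (3 of 5); an exact tie on an
even panel is excluded (conservative segmentation). Voting runs per
structure label. No claim is made that voting reduces *raw* outlier counts —
empirically it can increase them — only that shared support is required for
a voxel to survive, which tends to remove unshared PTV outliers.

## DVH and gamma conventions

- Plan normalization scales dose uniformly so the *median* PTV dose (D50%)
  equals the prescription (default 60 Gy = 30 × 2 Gy).
- Dx% ("largest dose received by at least x% of the volume") is the
  linearly interpolated empirical quantile of the voxel-dose sample at level
  1 − x/100. DVcc interpolates the descending-sorted sample at the
  fractional index n − 1 with n = volume / voxel size (so D1cc with
  integer n is exactly the n-th hottest voxel). Dmin/Dmax are raw voxel
  extremes. The two interpolation conventions differ slightly by design:
  each matches the natural counting definition of its metric. Structures
  smaller than 1 cc get D1cc = Dmin with an explicit warning flag.
- DVH curves use 0.1 Gy bins; metrics use the exact sorted sample, not bins.
- Gamma: global normalization (tolerance = dose_percent of the
  *prescription*, 1.8 Gy at 3%/60 Gy), 3 mm distance-to-agreement, 20 Gy
  low-dose cutoff applied to the **reference** grid's voxels. The evaluated
  dose is trilinearly interpolated on a lattice subdivided 3× per voxel;
  candidate offsets are visited in order of increasing distance with an
  early exit, truncated at 3 × DTA (configurable;
  `search_radius_factor=None` searches the whole grid and is what the
  brute-force oracle comparison uses). Computed fully in 3D.

## Synthetic data

Patient data cannot be shipped, so a generator module emulates the study
conditions:

- **Head phantom** — nested ellipsoids (body ⊃ brain ⊃ edema ⊃ GTV). Outer
  shells scale with the grid's physical extent; the lesion has fixed
  12 × 10 × 9 mm semi-axes, an 8 mm edema shell, and sits off-center with a
  ±3 mm seeded jitter. No anatomical realism beyond nesting and plausible
  scale is claimed.
- **Controlled experiments** — 61 scenarios: 20 equal-volume spheres
  (13 mm³ by default; the alternative 0.13 cm³ reading is a config override)
  stepped 10/20/30/40 mm outward along ±x, ±y, +z from the target surface;
  4 shapes (sphere + three 4:1-elongated orientations, equal volume) at two
  locations; 12 graded sizes at two locations matching the published
  4.21–186.45 mm³ voxel-volume ladder within one voxel (sizes 1–5 confined
  to a single axial slice, 6–12 spanning slices); and a 9-step ±4 mm margin
  ladder of the main target against one fixed small outlier (the 12.6 mm³
  one, configurable). Exact outlier coordinates were never published; the
  placements preserve the design intent (varying distance/direction) and
  are configurable.
- **Blob rasterization** — a blob is the k nearest voxel centers to the
  requested center under a shape metric, k = ceil(target / voxel volume):
  the smallest voxel count whose volume reaches the target, deterministic
  via (distance, index) ordering. Elongated blobs shrink the metric 4× along
  the principal axis (continuous aspect ratio 4, discretized ≥ 3) and are
  computed in a canonical frame and transposed back so equal-volume blobs
  along different axes are exact axis-swaps on symmetric grids.
- **Prediction sets** — per model and structure, the true mask shifted by up
  to one voxel plus N ~ Poisson(rate) injected spherical blobs; sizes
  log-normal (median 140 mm³ pre-margin, σ = 1, capped at 25% of the main
  lesion so the lesion always remains the largest component); centers
  uniform in distance over [10, 70] mm from the main structure, inside the
  brain; every blob kept disconnected from the main structure and from other
  blobs; failures after 25 retries are logged as dropped. The log records
  the *exact* voxel volume and closest center distance of every injected
  blob, making the downstream inventory exactly checkable. These defaults
  emulate the *PTV-surviving* outlier population of the published inventory
  (a few per structure, ~10³ mm³ scale after margin, tens of mm away); the
  real raw-to-PTV collapse of many tiny near-lesion fragments (1887 → 137)
  is not emulated, because the minimum injection distance exceeds twice the
  PTV margin by construction.
- **Dose surrogate** — prescription inside the PTV, exponential falloff
  exp(−d / 8 mm) outside. Only the monotone distance dependence matters
  downstream: a larger PTV (e.g. one carrying an outlier) strictly increases
  dose to surrounding tissue. Magnitudes, beam geometry, OAR trade-offs and
  optimizer behaviour are explicitly not modelled, so passing dosimetry
  tests demonstrate direction-of-effect and metric correctness, not clinical
  plan quality.

All randomness flows from a single integer seed through named
`numpy.random.Generator` instances; no global RNG state is touched.

## Aggregation

The model table sums outlier counts over cases per structure and pools each
model's PTV outliers across cases for mean/median size and distance (the
pooling convention; per-case averaging was the unstated alternative).
Summary statistics follow the published inventory's conventions: totals run
over all models including the ensemble; the "±" on distance/size is the
population SD over the six per-model means (this exactly reproduces the
published ±5.0 mm and ±95.6 mm³); per-model averages and the reduction
denominator use the five non-ensemble models, so

    reduction = 100 · (mean PTV outliers per model − ensemble count)
                    / mean PTV outliers per model,

which gives 33.88% for the published counts (printed as 33.8, a
truncation). The published dispersions ±10.5 and ±5.5 on the per-model
averages are not derivable from the table under any standard formula
(population/sample SD or SEM) and are not recomputed.

## Problem sizes

The controlled-experiment suite runs on a 128³ grid at 1.5 mm (192 mm
extent, large enough to host the 40 mm location ladder); the demo pipeline
and the injection-recovery study run 8–20 phantom cases on 64–72³ grids at
2 mm; gamma oracle comparisons use 12³ grids where the exhaustive
brute-force reference is cheap. These sizes are the package's demo
defaults; every driver accepts its own grid and case-count configuration.

## Known limitations

- No optimizer, no beam model: absolute dosimetric numbers from the
  surrogate have no clinical meaning.
- The mesh-volume surrogate reproduces the voxel/mesh *relationship*, not
  any TPS's printed mesh volumes.
- The phantom is a single-lesion geometry; multi-focal disease (where
  "largest component" is not the right notion of main structure) is out of
  scope.
- Gamma interpolation is fixed-subdivision trilinear; very steep gradients
  between subdivision points can bias γ slightly high, mitigated by raising
  `subdivision`.
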