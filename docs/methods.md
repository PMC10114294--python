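# Methods

This note documents the models, estimators and numerical choices behind
`fibmorph`, and what the synthetic-data tests do and do not demonstrate about
real FIB-SEM data.

## Scope and data model

The package operates downstream of semantic segmentation: its inputs are 3D
integer label volumes (one structure class per volume — nuclei, mitochondria,
cell junctions, actin bundles, lumen, cells) with explicit physical voxel
spacing. The canonical in-memory order is `(z, y, x)` with spacing in nm in
the same order; all *reported* coordinates are `(x, y, z)` in μm. Voxel
`(k, j, i)` has its center at `((i+0.5)s_x, (j+0.5)s_y, (k+0.5)s_z)`, so a
single-voxel object's centroid is its voxel center. Typical acquisitions are
anisotropic (e.g. 15×15×20 nm voxels binned ×2 to 30×30×40 nm), and every
estimator below works in physical units on anisotropic grids.

## Instance extraction

Semantic volumes are split into objects by 3D connected components
(default connectivity 26; 6 selectable). Components are computed within each
semantic label value separately, so touching objects of different classes
never merge. Objects touching the volume face are measured as-is but flagged
`border=true`, leaving the exclusion decision to the analysis; nothing in the
downstream statistics treats border objects specially by default.

## Morphometrics

* **Volume** `V_p` is exact: voxel count × voxel volume.
* **Centroid** is the unweighted mean of member voxel centers (no intensity
  weighting).
* **Surface area** `A_p` uses, by default, a local 2×2×2 configuration-weight
  estimator. Every 2×2×2 cell of voxel centers contributes a weight equal to
  the expected area of an isotropically random plane cutting the cell,
  conditional on the cell's 8-bit inside/outside pattern. The weights are
  derived numerically at first use for the *actual* cell box (so anisotropic
  grids need no resampling) from 200,000 random plane orientations × 16
  offsets, using the closed-form cut area (the derivative of the
  halfspace–box volume spline), averaged over the cell's symmetry orbit and
  the inside/outside complement, from a fixed internal seed — the derivation
  is deterministic and cached per spacing ratio. This construction is
  unbiased for planar surfaces; measured accuracy is ≤0.6% on digitized
  balls (radius ≥10 voxels) and ≤5% on axis-aligned boxes, on isotropic and
  anisotropic grids alike.

  A marching-cubes mesh estimator (`method="mesh"`) and naive exposed-face
  counting (`method="face"`) are provided as cross-checks. The raw mesh
  overestimates smooth surfaces by ~8–9%; smoothing the mask before meshing
  fixes balls but rounds box corners (−6…−16% on small boxes), which is why
  the configuration estimator is the default. Face counting overestimates
  smooth surfaces by exactly 3/2 in the continuum limit and is kept as a
  documented negative control.

  Caveat: the configuration weights are optimized for surfaces that are
  locally planar at the voxel scale. For objects a few voxels across
  (e.g. single-voxel junction rasterizations) the area estimate, and hence
  the sphericity, is not meaningful.

* **Sphericity** `Ψ = (6√π V_p)^{2/3} / A_p`, 1 for a mathematical sphere.
  With the default estimator, |Ψ−1| for digitized balls is 0.5%/0.2%/0.1% at
  radii 10/20/40 voxels, and Ψ of a digitized cube is within 0.03 of the
  closed form (π/6)^{1/3} ≈ 0.806. Ψ may exceed 1 by up to the estimator
  tolerance (0.05).
* **Volume outliers**: objects with `V_p ≥ factor × median(V_p)` per class;
  default factor 100 ("two orders of magnitude"), the regime of giant
  mitochondria.
* **Volume fractions**: per parent cell, child voxel volume inside the cell
  over cell volume. Child voxels outside every parent are reported in a
  `parent_id = 0` row, never silently dropped.

## Nearest-neighbour statistics

Because a ~40-nm z-pitch cannot reliably separate nearly-touching objects,
objects of the same class whose boundary-to-boundary gap is below 50 nm
(configurable) are excluded before NN statistics. The gap between two
objects is the minimum over boundary-voxel pairs of the center distance
minus the support width of one voxel box along the connecting direction —
i.e. the empty space between voxel faces, so two boxes separated by two
empty 20-nm slices have a 40-nm gap. Both members of a close pair are
removed (`exclude-both`); a `merge` mode that pools the pair's voxels under
one id exists but is off by default, since merging invents connectivity the
data cannot support. `min_gap = 0` disables the filter.

NN distances are exact 3D Euclidean distances between centroids in μm
(KD-tree, no approximation). Summaries report the fraction of objects
within each queried threshold (default 1 μm), percentiles by linear
interpolation between order statistics (the one percentile definition used
throughout the package), the median and the 25–75% interval. Statistics are
computed per acquisition volume and never pooled across volumes.

## Density maps

A structure mask is scanned on a regular node grid (default step 0.25 μm)
with a spherical kernel; a voxel belongs to the kernel iff its *center* lies
within the kernel radius of the node, which makes every node value exactly
reproducible by direct counting. The default radius is 1.0 μm (~4.19 μm³
sampling volume). The common description of this kernel as "a 1 μm diameter
sphere (~4 μm³)" is internally inconsistent — a 1-μm-diameter sphere holds
0.52 μm³ — and the volume figure is taken as operative; the literal diameter
reading (radius 0.5 μm) is available via configuration.

Edges: under the default `renormalize` policy a node's value is the occupied
in-kernel voxel volume divided by the *in-bounds* kernel volume, and nodes
with less than 50% kernel coverage are marked invalid; `strict` invalidates
any clipped node. Values are in [0, 1] wherever valid, and adding occupied
voxels never decreases any node value.

Co-occurrence of two maps (e.g. junctions vs actin bundles) is summarized by
the Pearson correlation over jointly valid nodes, with a companion
high-density co-occupancy fraction (both maps above their own quantile,
default 0.75).

## Preservation and packing statistics

Tile scores are an input: each TEM tile of an organoid is scored
damaged/intact by eye, and the preserved fraction is intact over total tiles.
Packing density is organoid cross-sectional area divided by cell count
(approximated by counting nuclei), in μm²/cell. Groups are summarized by
median/quartile/min/max box statistics (same quartile rule as above), and
the packing–preservation relationship by the Pearson product-moment
correlation. No automated damage detection is attempted.

## Synthetic organoid generator

The generator provides ground truth for every statistic above. It emulates
three packing morphologies: `monolayer` (one Voronoi-partitioned cell shell
around a single ellipsoidal lumen; lumen fractions up to ~0.6), `compact`
(Voronoi partition of a filled ellipsoid, no lumen) and `mixed` (compact
body with 2–4 embedded lumina). Cell seeds are spread by Mitchell
best-candidate sampling and voxels assigned to the nearest seed in physical
coordinates. The monolayer lumen is an exact scaled copy of the organoid
ellipsoid, so the achieved lumen fraction lands within voxelization error of
the target (post-condition: ±0.05).

Per cell the generator can place:

* one **nucleus** — an ellipsoid at the cell's deepest interior point
  (distance-transform argmax) with jittered semi-axes and random rotation;
  when a target nuclear volume fraction is requested the axes are rescaled
  (up to 6 fixed-point iterations on the rasterized intersection) to within
  1% of the target;
* **mitochondria** — spheres with log-normal volumes (median, log-σ
  configurable; defaults 0.2 μm³, 0.8), placed at interior points with a
  clearance margin and mutual separation so connected components recover
  them exactly; optional planted outliers of `factor ×` the median volume;
* **junctions** — a hard-core point process on the cell–cell interface
  voxels (minimum separation 2·radius plus a voxel-scale margin so
  rasterized objects never touch). When a target 90th-percentile NN distance
  is requested the process is tuned by bisection: clustering (a
  parent–offspring process with a gathering radius) pulls the p90 below the
  uniform hard-core baseline; increasing the hard-core radius lifts it
  above, but only by a few percent before random sequential placement
  saturates — infeasible targets raise an explicit error rather than
  returning an off-target process. An `apical` placement mode restricts
  junctions to interfaces within a configurable band of the lumen surface;
* **actin bundles** — ~1-μm fibers seeded on the lumen-lining membrane,
  oriented along the local inward normal (gradient of the lumen distance
  transform), protruding into the lumen.

All randomness flows from one `numpy` generator seeded by the spec; the same
spec and seed give bit-identical volumes.

The tile-table generator draws per-organoid preservation rates (group mean
plus optional organoid-level Gaussian jitter, clipped to [0.02, 0.98]),
i.i.d. Bernoulli tile scores, and packing densities linearly coupled to the
observed preserved fraction plus Gaussian noise. Its asymptotic Pearson R is
available in closed form (`expected_pearson_r`), which the recovery tests
compare against.

### What the synthetic scenes do not emulate

Grayscale EM texture, segmentation errors (false merges/splits beyond an
optional label-noise hook), freezing damage, curtaining, irregular cell and
nucleus shapes (clefts, grooves, polynucleation), mitochondrial networks,
and anything about the statistics of real junction clustering beyond the
controllable NN scale. Passing recovery tests therefore demonstrates that
the *measurement pipeline* is correct and unbiased under known geometry —
not that real organoids have these parameter values.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script scenes are sized so each statistic is
measured where it is meaningful while the whole suite stays desk-scale: the
junction-recovery scene is a 32.5-μm cube (260³ voxels at 125 nm) with 250
cells and 5,000 junctions — large enough that a 1.0-μm p90 is geometrically
feasible on the available interface area (~13,000 μm²); morphology,
containment and co-occurrence checks use 48³–120³ scenes; tile-table
statistics use the group sizes of the motivating study (6–11 organoids,
50–231 tiles each, 50 organoids for correlation recovery). Oracle
equivalence runs on 64³ volumes (20 seeds, both connectivities) and n = 2,000
point sets.

## Known limitations

* Surface areas (and Ψ) of objects only a few voxels across are unreliable
  (see above); the junction NN analysis deliberately uses centroids only.
* The proximity-exclusion gap uses voxel-center geometry with a support-width
  correction; for gaps much smaller than a voxel it saturates at 0.
* The junction process tuner targets one quantile (p90) of the NN
  distribution; it does not control the full distribution shape.
* MRC output is limited to integer modes 0/1/6 (≤16-bit label ids); use
  HDF5 or TIFF for larger id ranges.
* Density maps are computed by exact per-node counting; at very fine steps
  over large volumes this is the dominant pipeline cost.
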