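# Methods

`alveoquant` quantifies terminal lung airspaces on high-resolution
tomographic slices and tests how their number and size respond to a
decremental positive end-expiratory pressure (PEEP) maneuver.  This note
documents the models, the algorithmic choices and the limits of what the
synthetic validation can show.

## The measurement problem

At ~48 µm isotropic voxels, rabbit alveoli (~110 µm across) are only two to
three voxels wide, and phase-contrast imaging wraps every gas/tissue
boundary in a one-voxel dark/bright fringe pair.  A plain density threshold
therefore cannot delineate alveolar boundaries.  The operational unit is the
*airspace*: a gas-density region anatomically separated from its neighbours
by septal structures of tissue-like density.  One airspace is not claimed to
equal one anatomical alveolus.

Two summary metrics are computed per (animal, PEEP, slice, ROI) cell:

* **ASnum** = NAs / analyzed volume (units/mm³), where NAs is the airspace
  count and the analyzed volume is the slab spanned by the cell's analyzed
  voxels (count × voxel_side³);
* **ASdim** = gas area / NAs (voxels of in-plane area), undefined when
  NAs = 0.

By construction ASdim × NAs equals the gas area exactly, and because an
airspace is *counted* in the band holding its detection peak while its
*area* accrues to every band it overlaps, NAs is additive across bands and
gas area is conserved.

## Detection chain

All analysis is strictly 2D per slice; the cranio-caudal stack only pools
observations.  The stages and their defaults:

1. **Non-ventilated exclusion.**  Flooded/atelectatic regions on the
   perimeter of the ventilated parenchyma are removed before any counting.
   Candidates are connected components of tissue-density voxels (above a
   per-slice Otsu threshold by default) surviving a morphological opening
   with a 13-voxel square.  The opening encodes a scale separation: septal
   walls are tissue-dense but only a few voxels thick, flooded caps span
   millimetres.  A component is excluded when it reaches within the opening
   scale of the mask perimeter (flooded regions continue into the chest
   wall; interior dense structures such as vessels are retained), exceeds
   300 voxels, and is ≥90% tissue-dense.  No denoising is applied here: the
   gas/tissue class gap is ~10 noise standard deviations at the 10%-contrast
   noise level studied, so the raw threshold map is already clean.
2. **Top-hat enhancement.**  A black top-hat ladder
   (`closing(img, disc(r)) − img` for r = 2, 3, 4, 6 voxels, voxelwise
   maximum over the ladder) turns dark gas pockets of any bracketed size
   into positive peaks.  The radii default to that ladder because the
   ladder must bracket the airspace scale after fringe blur; all four are
   configuration parameters.  Before the ladder the slice is smoothed with
   a σ = 0.8 voxel Gaussian.  A 3×3 median was tried first and rejected on
   measurement: it erases the one-voxel fringe rim and deletes airspaces
   below ~5 voxels entirely, producing a spurious count-loss trend with
   deflation; the sub-voxel Gaussian cuts voxel noise about threefold while
   a one-voxel gas pocket at full contrast still clears the peak threshold.
3. **Peak counting (NAs).**  Local negative-intensity peaks of the original
   image are counted as regional maxima of the enhanced image with
   prominence ≥ `h_depth` (h-maxima suppression; default 5% of the 16-bit
   range, i.e. 3277).  A connected plateau counts once, at its centroid;
   maxima closer than 2 voxels merge keeping the higher one, ties broken by
   lowest (row, col) for determinism.
4. **Delineation.**  Each peak grows into the connected region of voxels
   strictly below the tissue threshold (per-slice Otsu moved to the
   midpoint of the inter-class gap, so strict comparisons are stable).
   Peaks at tissue density are dropped and reported.  Peaks falling inside
   *one* connected sub-threshold region are merged: a valley between two
   enhancement maxima separates airspaces only when it is a tissue-density
   ridge — otherwise both maxima sit in one gas pocket, typically opposite
   arcs of a fringe ring.  This merge implements the "density and
   morphology simultaneously" criterion; after it each gas region holds at
   most one seed, so the watershed partition of contested voxels is
   degenerate and regions are simply their seeded components.

Known limit: with the merge rule, two anatomical alveoli joined by a
sub-threshold (partial-volume) septum count as one airspace.  The phantom
renders crisp septa and cannot probe this regime; on real data the counts
are a lower bound at fixed threshold.

## Regions of interest

The analyzed parenchyma is banded by per-slice Euclidean distance from the
pleural surface: subpleural [0, 2) mm, mantellar [2, 4) mm, core [4, ∞) mm.
The offsets are band inner edges; half-open intervals make the partition
exact (disjoint and exhaustive), and the core band is uncapped.  Distances
follow the voxel-centre convention (a boundary voxel is one voxel side from
the exterior), and excluded non-ventilated regions count as lung interior
when locating the pleural outline — flooding does not move the pleura.

## Statistics

Pooled per-slice observations (no per-animal averaging) enter ordinary
least-squares regressions of each response on the applied PEEP, per ROI.
The regressor defaults to the *measured* end-expiratory pressures
(12.4, 9.6, 6.8, 4.1, 1.1 cmH₂O) rather than the nominal dial ladder
(12 … 0): measured pressure is what the parenchyma saw, and the reference
subpleural ASdim slope of 0.41 voxel/cmH₂O is reproduced only under this
reading.  Regression pairs are compared with the extra-sum-of-squares
F-test (common line vs separate lines, F with (2, n−4) df), restricted to
regressions that are themselves significant.  Paired variables use the
Wilcoxon signed-rank test: exact 2ⁿ sign-flip enumeration of the positive
midrank sum for up to 15 non-zero pairs (ties handled exactly through
midranks; two-sided p as the symmetric tail |W−μ| ≥ |w−μ|), a
tie-corrected normal approximation above.  Families of comparisons are
Bonferroni-controlled at α = 0.05 with rejection at p ≤ α/m.  A perfectly
constant response (a fully de-aerated stack) yields slope 0 with p = 1
rather than an undefined fit.

## The phantom

The generator emulates what the deflation study measures, not the imaging
physics.  Each slice is an independent tessellation of a disc-shaped
parenchyma section: airspace sites on a jittered hexagonal lattice, each
carrying a near-circular gas region whose radius is drawn (10% CV by
default) and then clamped so that at least one septal thickness of tissue
separates it from every neighbour, from the pleural boundary and from any
flooded cap.  The lattice-plus-clamping construction was chosen over a
centroidal Voronoi tessellation because it controls the two quantities the
contracts care about — the realized region count (exact) and the mean
equivalent diameter (within 15% of the request) — while producing the same
"gas regions separated by septa" morphology.  A flooded cap is a single
circular segment of the requested area fraction at a seeded orientation,
constant across slices; the geometry of real flooding is not modelled
beyond "peripheral, gas-free, tissue-dense".

Rendering assigns gas and tissue grayscale levels (defaults 20000/45000 on
the 16-bit scale), adds a one-voxel dark/bright overshoot pair of
configurable amplitude at every gas–tissue boundary (the phase-contrast
signature), then seeded Gaussian noise; out-of-range values are clipped and
counted.  There is no point-spread blur, no reconstruction artifact, no
beam physics: septa render crisp.  Consequently, passing tests demonstrate
correctness of the counting/delineation logic and its noise robustness, not
performance under partial-volume blur.

Deflation mechanisms follow the classical four-way taxonomy; two are
modelled.  *Balloon*: every open airspace keeps its identity and its area
scales to (1−f), implemented by retaining the area-quantized nearest-centre
voxels (exact to ±1 voxel).  *Derecruitment*: a seeded, nested subset of
round(f·N) airspaces fills with tissue; survivors are untouched.  *Mixed*
splits f 50/50.  Shape change and crumpling are reserved names.  Fractions
map to pressure only through the caller's table; no pressure–volume
physiology is implied.

A deflation series applies each level's fraction to the *same* base truth,
so ground truth is retained per level.  Render noise is keyed by the
phantom seed alone, so identical truths render identically across levels —
a zero-deflation series is exactly level-invariant, which pins the null of
the regression layer.  Per-slice fraction jitter (f·(1+0.5·z) by default in
the study preset) supplies the level-to-level scatter and reproduces the
observed pattern of between-slice spread growing as pressure falls,
emulating fluctuating local recruitment in injured lungs.

**Study preset** (`ards_phantom_spec`): 5 mm section radius, 700 airspaces
per slice (≈190/mm³ of analyzed slab), 194 µm mean diameter (≈13-voxel
areas at full recruitment), 95.4 µm septa, fringe 4000, noise 2500 (10% of
contrast), with per-slice size (8.5% CV) and count (15% CV) heterogeneity;
`simulate_experiment` adds animal-level count/size effects.  The deflation
profile (0, 0.15, 0.31, 0.39, 0.42) makes the mean airspace area fall from
~13 to ~7.6 voxels across the 12→0 cmH₂O ladder — the magnitude reported
for lavage-injury rabbit lungs.  Simulations in the test suite and the
acceptance script run 2 animals × 20 slices × 5 levels (n = 200 per
regression), a scale at which the balloon/derecruitment contrast is
overwhelming while a full run stays under a minute.

## Numerical conventions

Coordinates are 0-based (slice, row, col); areas in voxels; thresholds in
raw grayscale; lengths in µm (offsets in mm).  Grey morphology clips
neighbourhoods at the image border (out-of-bounds voxels never contribute),
which is what the brute-force oracle in the tests reproduces exactly.
Out-of-mask voxels are replaced by the in-mask maximum before closing so
dark structures beyond the parenchyma cannot leak enhancement in.  All
tie-breaks (plateau reduction, peak merging, balloon voxel retention) are
lexicographic on (row, col), making every output a pure function of inputs
and seeds; repeated runs are byte-identical, which the manifest checksums
record.

## Known limitations

* No 3D connectivity anywhere — deliberate, matching per-slice pooling; an
  airspace spanning slices is counted once per slice.
* The exclusion step over-reaches by a thin tissue halo (≲ one opening
  scale) around true flooded caps and cannot find non-peripheral flooding.
* Exact count recovery requires septa ≥ 2 voxels and airspace diameters
  ≥ 4 voxels; smaller structures are below the stated resolvability limit
  and vanish from counts (this is also why deep balloon deflation of
  barely-resolved airspaces eventually bleeds into an apparent count loss).
* Plain OLS across pooled slices ignores within-animal correlation, in
  keeping with the simple-regression design it mirrors; the animal column
  is retained so users can stratify or fit mixed models elsewhere.
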