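# Methods

`filarch` quantifies the 3D architecture of traced cytoskeletal filament
networks at the β-cell periphery — the kind of data produced by
cryo-electron tomography segmentation pipelines — together with the 2D
skeleton metrics used for super-resolution fluorescence images of the
actin meshwork. This note documents the models, conventions, parameters
and their defaults, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Coordinate and unit conventions

All geometry is in nanometers. Unit conversion happens exactly once at
ingest: filament tables may be given in voxels (scaled by an explicit
voxel size), and MRC mask headers carry their voxel size in ångströms,
converted to nm on read. Volume grids are indexed `[z, y, x]`; the
physical position of voxel `(i, j, k)` is its **center**,
`origin + (index + 0.5) · voxel_size`. Masks must be isotropic;
anisotropic volumes are rejected rather than silently resampled, because
every distance threshold in the analysis is a physical length.

## Filament geometry

A filament is an ordered 3D centerline polyline with a class label
(actin or microtubule). Before any distance statistic, filaments are
resampled to equal arc-length chains at a 4 nm interval. The terminal
node of the original polyline is appended when its arc distance from the
last regular sample is at least half the interval, which keeps total
length coverage unbiased; total resampled length therefore agrees with
the true arc length to within one interval.

A filament's **direction** is the unit chord between its two original
end nodes, not a local tangent — short traced segments (one to a few
tracing units of 60 nm) are nearly straight, and the chord is the
natural orientation of such a segment. A per-segment mean direction is
available behind a flag but is not the default.

Angles come in two flavors:

* **undirected** pair angle `arccos |a·b| ∈ [0°, 90°]` between two
  chords — used for the filament–filament angle maps;
* **directed** angle `arccos(a·b) ∈ [0°, 180°]` — used only for
  PM-anchored filaments, whose vector has a defined sense (from the
  membrane-near end to the far end).

Orientation relative to the plasma membrane is the chord's elevation out
of the tomogram XY plane, `arcsin |c_z| ∈ [0°, 90°]`. This uses the
fixed z-normal as the membrane proxy (peripheral tomograms are acquired
with the membrane roughly in-plane); it is the one quantity that is not
invariant under arbitrary rigid motions, which is documented behavior.
Filaments below 45° are classed **parallel**, at or above 45°
**quasi-orthogonal**; the boundary value 45° goes to the
quasi-orthogonal class (closed-right rule, fixed and documented because
the two ranges meet at 45°).

## Distance queries

Filament–filament distances are per-resampled-point nearest-neighbor
distances to all points of all *other* filaments of the same class,
computed with a KD-tree whose result equals exhaustive search exactly
(ties broken by lowest filament id, then point index). Point-to-mask
distances use a Euclidean distance transform of the voxel grid sampled
trilinearly at the query points; points inside the mask are at distance
0 (contact, not signed depth), and the sampled field agrees with direct
nearest-boundary-voxel search to within one voxel diagonal. Points
falling outside the grid are evaluated at clamped coordinates and
flagged in the output.

## Analyses and their defaults

| parameter | default | unit | role |
|---|---|---|---|
| resampling interval | 4 | nm | point spacing for all distance statistics |
| orientation class boundary | 45 | deg | parallel vs quasi-orthogonal |
| anchor threshold | 60 | nm | end-point-to-PM distance (`≤`), one tracing unit |
| neighbor threshold | 120 | nm | near-end separation (`<`), two tracing units |
| proximity cutoff | 200 | nm | reporting cutoff for granule distances |
| actin / MT granule histogram bins | 75 / 100 | nm | distance histograms |
| pairwise distance bin | 10 | nm | actin–actin histograms |
| anchored-angle bin | 15 | deg | directed-angle histograms |
| cylinder radii (actin / MT) | 4 / 7.5 | nm | volume-ratio model |
| bundle box | angle ≤ 15°, distance 8–17 nm | | bundle operationalization |

The **volume ratio** models each centerline as a cylinder of the nominal
tracing radius; it is additive over filaments and invariant under rigid
motion. A voxel-count mode is the natural alternative when a filament
voxel mask exists, but centerlines plus nominal diameters are the only
guaranteed inputs.

The **bundle criterion** is an explicit box in (pair angle, nearest
distance) space — near-parallel pairs at the 12–13 nm packing distance —
and is labeled an operationalization: bundles are defined by a density
peak, and the box is the reproducible stand-in for "inside the peak".
Both thresholds are configuration, echoed into output provenance.

**Anchoring** measures both end nodes of each actin filament against the
PM surface (nearest boundary-voxel center); a filament is anchored when
the smaller distance is ≤ 60 nm. "Same membrane" is operationalized as
the same 26-connected component of the PM mask. Neighboring anchored
filaments (same component, near-end separation < 120 nm) contribute
directed angles; both ordered directions of a pair are recorded so
histograms split by the host's orientation class are well defined.

**Periphery height** is the difference between the mean z of boundary
voxels of the uppermost and lowermost PM components. For tilted parallel
membranes this z-based definition reads `separation / cos(tilt)`, which
is accepted and documented; the original measurement procedure for this
quantity is not specified anywhere, so one defensible rule is fixed.

**Architecture classification** compares anchored directed-angle
histogram mass in [60°, 90°) against [0°, 30°) among quasi-orthogonal
hosts: crossing-dominated networks ("netlike", the granule-blocking
state) beat aligned radial projections ("blooming", the
transport-permissive state). By default only pairs whose neighbor is
also quasi-orthogonal enter the rule — the contrast describes how the
reoriented filaments relate to each other, and mixed pairs with parallel
bystanders blur it.

**Organelle proximity** distances run from resampled points to the
nearest granule surface (or MT centerline for the actin–MT analysis,
with a per-filament minimum — the "shortest MT distance"). The 200 nm
cutoff (one tracing unit plus the reach of myosin V and its unresolved
tail) is applied at reporting time, not at record generation, so the
raw tables support sensitivity analyses. Actin–MT distances are
centerline-to-centerline; an optional tube-radius correction exists but
defaults off.

## 2D meshwork metrics

Subsection images (0.97 µm² at 31.3 nm/pixel) are binarized with the
IsoData automatic threshold (the "default" threshold of the common
image-analysis tools), thinned to a one-pixel skeleton, and decomposed
into branches between endpoints and junction clusters. A junction pixel
has ≥ 3 skeleton neighbors (8-connectivity); 8-adjacent junction pixels
merge into a single junction, which matches how thinning produces small
junction blobs at crossings. Branch length sums inter-pixel steps (1 px
orthogonal, √2 px diagonal) including the steps that attach the branch
to its junction clusters, plus the orthogonal steps *inside* each
cluster (a crossing's cluster spans the crossing pixel and its arm
neighbors; its diagonal intra-cluster adjacencies are thinning
artifacts, not line geometry). Branches of length ≤ 1 pixel are
discarded, which removes isolated-pixel artifacts. With these
conventions the measured length of an axis-aligned digital line network
equals its analytic length exactly.

## Synthetic scenes: what they emulate, and what they do not

The generator builds tomogram-equivalent scenes with known ground truth:

* two parallel PM voxel slabs (13.4 nm thick) bounding a periphery of
  configurable height (basal preset 190.5 nm, second-phase 258.4 nm);
* actin filaments with an exact quasi-orthogonal count
  (`round(f · n)`), mostly PM-anchored (default 90%), at a realistic
  density — 300 filaments in a 1.8 × 1.3 µm field, matching the scale
  of ~290 filaments per binned peripheral tomogram;
* bundles as ladders of (default five) exactly parallel filaments at
  12.5 nm spacing with 0.4 nm Gaussian jitter;
* netlike clusters (pairs of quasi-orthogonal anchored filaments
  crossing at directed angles in ≈ 63–84°) or blooming clusters
  (near-parallel radial projections at steep elevations, 58–78°, mutual
  angles < 15°, which also gives the second-phase condition its excess
  of filaments above 60° elevation);
* anchored antiparallel pairs of parallel-class filaments, which
  populate the 150–180° peak of the parallel-host angle histogram;
* spherical insulin granules (radius 150 ± 25 nm — a plausible granule
  scale, a free parameter rather than a literature value) rasterized as
  a labeled mask, and a few gently curved microtubules.

Placement uses a rejection sampler with segment-to-segment clearance
(20 nm plus ladder halos) so that independent structures do not fake
bundle contacts; at the default density the field is near 2D packing
capacity and a few structures are placed without full clearance (a
warning reports how many). Quasi-orthogonal filaments are always
anchored: in a ≤ 260 nm gap, a ≥ 120 nm filament at ≥ 45° elevation
cannot keep both ends 60 nm away from both membranes — consistent with
the ~90% anchored fractions seen in thin peripheries. Their lengths are
capped (far end ≥ 70 nm below the opposite membrane) to keep the
near/far end assignment unambiguous, which limits them to roughly
90–140 nm in the basal-height preset.

Scenes are deterministic given the seed, with independent random
streams per component (filaments, granules, microtubules), so changing
the granule count does not perturb the filament layout. Default mask
voxel size is 2.68 nm (twice the 4×-binned tomogram pixel of 1.34 nm),
which keeps full-volume distance transforms tractable without changing
any physical threshold; the I/O layer accepts masks at any isotropic
voxel size.

Filaments are straight segments — at 120–600 nm lengths, actin's ~10 µm
persistence length makes curvature negligible — so the generator does
**not** emulate: curved or branching filaments, membrane curvature
(slabs are flat), segmentation noise such as broken or merged traces,
missing-wedge anisotropy, or partial granule membranes. Passing the
recovery suites therefore demonstrates correctness of the measurement
chain on clean geometry, not robustness to tracing errors.

The 2D meshwork generator draws axis-aligned horizontal/vertical line
networks whose analytic skeleton length and crossing count are exact
under the length conventions above; line spacing ≥ 4 px keeps adjacent
junction clusters separate and ≥ 3 px end overhangs keep terminal
branches above the 1-px filter. Oblique lines are deliberately excluded
from the generator: the 8-connected geodesic of an oblique digital line
overestimates its Euclidean length by up to ~8% (chessboard metric),
which would poison the exactness of the ground truth. Rendering at
width 1 with optional Gaussian noise; the noiseless render is the
reference condition for exact junction recovery.

## Statistics

Group comparisons are thin wrappers with a fixed reporting schema:
one-way ANOVA with Tukey HSD over all pairs, Student's two-sample
t-test, and the variance-ratio F-test, always reported together with
group means ± SEM. The degenerate identical-groups case (F numerically
just below zero) is clamped to F = 0, p = 1. The 2D kernel density used
to color scatter maps standardizes both axes to unit variance first —
degrees and nanometers are incommensurate — and uses Scott's-rule
bandwidth unless overridden; the bandwidth and scaling are recorded in
provenance, and no claim is made that they match any particular
published density map.

## Problem sizes used by the recovery suites

The acceptance checks run entirely on synthetic scenes: orientation
recovery uses 100 scenes of 400 filaments per generating fraction
(masks off — orientation needs only chords); architecture
discrimination uses 100 + 100 half-field scenes (0.9 × 0.65 µm, 75
filaments — the study density on a quarter of the field of view);
bundle-spacing recovery uses full-size scenes; meshwork recovery uses
24 noiseless subsections; the type-I error check uses 100 repeats of
4-vs-4 scene comparisons. `scripts/acceptance.py` re-measures the same
quantities at slightly smaller replicate counts and prints them with
the problem size next to each value.

## Known limitations

* The PM-plane proxy is the tomogram XY plane; strongly curved or
  tilted membranes bias orientation angles (a local plane-fit mode
  exists for the curious but is not validated against any reference).
* Periphery height assumes exactly two membrane components; grazing
  sections that merge top and bottom membranes into one component are
  rejected with an explanatory error.
* The bundle box and the architecture rule are operationalizations of
  qualitative descriptions; their thresholds are configuration, not
  discoveries.
* Real segmentations (broken traces, duplicated points, vendor offset
  conventions) are accepted by the readers but the analysis itself does
  not attempt to repair them beyond dropping duplicated consecutive
  points in spatial-graph imports.
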