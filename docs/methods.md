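# Methods

This note records the models and procedures `mitoscore` implements, the
conventions chosen where the published material leaves them open, and what
the synthetic fixtures do and do not establish about behavior on real data.

## Data model

Volumes are 3D arrays ordered (z, y, x) — the thick serial-section axis
first — with physical spacing in nm in the same order; the default is
(30, 8, 8) nm, the common serial-section EM convention. Label 0 is
background; instance ids are positive integers and need not be consecutive
(all metrics consume an instance index, never assume density). Bounding
boxes are half-open 0-based intervals. I/O supports HDF5 (dataset name
configurable, default `main`, spacing stored as a dataset attribute) and
multi-page TIFF with a JSON sidecar carrying `spacing_nm`. Integer grids
round-trip bit-exactly; probability grids are stored as float32.

## Overlap and IoU

The contingency table is built in one linear pass of joint-label counting
over paired voxels (the standard sparse construction), never by
re-rasterizing per-instance masks; IoU is computed lazily from the counts
|A∩B| / (|A| + |B| − |A∩B|). This makes the table the single source of truth
for matching, AP and association, so the three metric families can never
disagree about what overlaps what.

## Hungarian matching and accuracy

The assignment cost is C(i,j) = −[IoU ≥ T] − IoU/(2N) with
N = min(#pred, #gt) and T = 0.75 by default. The second term is read as a
*division* by 2N: the typeset source formula is ambiguous between
multiplication and division, but only a term strictly below 1/2 per pair
keeps the indicator dominant, so the assignment first maximizes the number
of above-threshold matches and uses total IoU only to break ties among
equally thresholded alternatives. The rectangular problem is solved with
`scipy.optimize.linear_sum_assignment`; since every real entry is ≤ 0,
leaving an instance unassigned is equivalent to matching it to a zero-cost
dummy. Assigned pairs with IoU ≥ T are TP; all other predictions FP, all
other GT FN. Ratios with zero denominators are reported as 0.

Per-group scores bin TP and FN by the GT instance's size group. For FP the
choice is genuinely open; `mitoscore` defaults to binning a false-positive
prediction by its *best-overlapping GT instance's* group, falling back to
the group computed from the prediction's own mask when it overlaps nothing.
This is the only convention consistent with the per-group precision values
of the published toy-scene table (a split piece of a large instance counts
against the large group, a pure background blob against its own size); the
pure own-mask alternative is available as `fp_bin="pred"`.

## AP-75 with size as confidence

Bottom-up decoders emit no confidence, so predictions are ranked by voxel
count, ties by ascending id. Matching inside AP is the standard *greedy*
rank-order rule (each prediction claims its highest-IoU unclaimed GT if
IoU ≥ T, ties toward the lowest gt id), deliberately distinct from the
Hungarian matcher, which is reserved for the accuracy score. "Larger than
the threshold" is implemented as ≥ T so that the two matchers agree on
boundary pairs. AP is the 11-point interpolated average; the all-point
integral is exposed for diagnostics only. Per-group AP restricts both sides
to the group before ranking; this reproduces the known size-confidence
artifact in which a small GT merged into a larger prediction becomes an FN.

## Association taxonomy

The association graph contains every pair with positive overlap
(`min_overlap` = 1 voxel by default; it is exposed because single-voxel
touches can inflate many-to-many on noisy decoders, but the default
preserves the strict definition). Categories follow the reciprocal-mapping
definitions; under-segmentation is assigned per GT, i.e. *every* merged GT
instance receives the label. Non-background percentages use the GT count as
denominator and sum to 100%; background uses the prediction count and is
reported overall only, because a background or merged prediction has no
unambiguous GT group (per-group background cells are intentionally absent).

## Cable length and grouping

Cable length is the total physical length of the instance's 3D skeleton.
The published footnote defining it procedurally is not reproduced in the
source text, so the implementation fixes a concrete, deterministic
definition: `skimage.morphology.skeletonize` (3D thinning) on the voxel
grid, a 26-adjacency graph over skeleton voxels with Euclidean edge weights
under the anisotropic spacing, and the sum of minimum-spanning-tree edges
per connected component. Thinning on the grid (rather than after isotropic
resampling) avoids interpolation artifacts and keeps results deterministic;
the spanning tree prevents double-counting in thick junction clusters.
Straight-bar fixtures give exact analytic lengths ((k−1) × spacing); length
is linear in spacing and invariant under matched axis permutations.
Thresholds: small ≤ 1 µm, large ≥ 4 µm, medium strictly between (boundary
values land in small/large respectively). The legacy voxel-volume grouping
keeps the same boundary semantics but ships no default thresholds — they
must come from config, since no published cutoffs are restated here.

## Split/merger decomposition

Over-segmentation pairs form the split set S, under-segmentation pairs the
merger set M. Many-to-many pairs are routed by comparing GT-side fan-out
|A(g)| with prediction-side fan-in |A′(p)|: fan-out ≥ fan-in → split, else
merger (ties to S). The literal published set definitions attach the
opposite inequality to splits, contradicting their own prose (a split is one
GT fanning out over several predictions); the implementation follows the
prose semantics and keeps the literal form behind `as_printed=True`.
Histograms bin GT cable length into 15 equal-width linear bins ("evenly
divided"; nothing suggests log spacing) and report per-bin mean/sd of split
piece counts and merger fan-ins plus occupancy.

## Watershed decoder

Seeds are connected components (26-connectivity by default, configurable to
6) of (foreground ≥ θ_seed) AND (contour < θ_contour); the conjunction is
the only combination of the two thresholded maps that yields distinct,
non-touching seeds, matching the triple-threshold description of the
challenge post-processing. The watershed floods 1 − foreground from the
seeds, confined to the mask foreground ≥ θ_fg (hence the constraint
θ_seed ≥ θ_fg); instances below `min_voxels` (default 1024, "fewer than"
semantics, exactly 1024 kept) are removed. All thresholds are inclusive
(≥). Presets: `mitoem-h` (0.7, 0.6, 0.6) and `mitoem-r` (0.85, 0.6, 0.8)
for (seed, contour, foreground). An optional per-x-slice (z, y)-plane median
filter reproduces the 2D baseline's post-filtering. The scikit-image
watershed gives deterministic plateau handling: identical inputs produce
identical labels.

## Synthetic scenes

The six-instance toy scene encodes only the outcome-determining facts of
its published description: two small, three medium, one large GT by cable
length; one small and two medium GT exactly matched (IoU = 1 ≥ 0.75); the
remaining small+medium pair covered by one merged prediction; the large
instance covered by four disjoint pieces overlapping only it. Geometry is
bars of 3 × 3 voxel cross-section along z (20 / 50 / 160 voxels at 30 nm →
0.57 / 1.47 / 4.77 µm, safely inside the small/medium/large bands; thinning
preserves the centerline exactly). The merged prediction's IoU with its
medium constituent is 450/630 ≈ 0.714 < 0.75 because the merged instances
are comparable in size — a construction constraint asserted in the tests.
Each split piece (40 voxels ≈ 1.17 µm) is medium in its own right, so the
large group contains no predictions and its precision is 0/4 = 0. The
false-positive count is a free parameter: 17 blobs reproduce the published
total precision 3/25 = 0.12 and accuracy 3/28 ≈ 0.10; the published
background percentage (65.4%) is mutually inconsistent with that precision
under any integer count and is therefore not targeted — with 17 FPs the
scene yields 17/25 = 68%.

Random scenes place blobs or tubes in disjoint lattice cells (guaranteed
separation), and `ErrorPlan` injects k-way slab splits, merges and
background FP blobs with full seeded determinism, so association output can
be checked against the planted plan exactly. Probability rendering produces
a smoothed foreground indicator and a one-voxel boundary-shell contour map
with optional truncated Gaussian noise. These fixtures emulate the *label
topology* of real segmentations, not their appearance: no EM texture,
irregular morphology, anisotropic blur or correlated network errors.
Passing tests therefore establish correctness of the metric computations
and decoder mechanics, not segmentation quality on real micrographs.

## Problem sizes and numerics

The validation suite runs at desk scale by design: toy scene 170 × 40 × 40,
random scenes up to 96³, 200 oracle scenes at 8³ with ≤ 6 instances per
side (where exhaustive assignment enumeration is feasible), 50 planted
error plans. Whole-dataset volumes (Gigavoxel scale) are out of scope — no
chunked or out-of-core processing is provided. Percentages are kept at full
precision in JSON and rounded to one decimal (scores to two) only in
human-readable views. Degenerate inputs are defined everywhere: empty
prediction or GT sides yield zero scores and missing/background reports
rather than errors; 0/0 ratios are 0 by convention.
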