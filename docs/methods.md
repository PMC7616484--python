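# Methods

This note records the models, conventions and numerical choices behind
`imflow`, what the synthetic generators do and do not emulate, and the known
limitations.

## Coordinate stores and the memory-cost model

An object's voxels can be held in three interchangeable structures:

- **Pointlist** — an explicit set of (x, y, z) integer triples. Natural for
  spots and skeletons; modules that produce such one-pixel-scale output
  (skeleton decomposition) always emit pointlists, while general object
  detection exposes the choice to the user.
- **Quadtree** — one tree per occupied z-slice. The root square is the
  smallest power of two covering max(width, height); the padding beyond the
  image is treated as uniform background and is never emitted as a
  coordinate. Subdivision into quadrants stops as soon as a node is uniformly
  foreground or background. Trees are kept *maximally merged*: no subdivided
  node ever has four uniform children of one state, and incremental voxel
  insertion re-merges affected ancestors immediately, so the invariant holds
  unconditionally, not just after bulk construction.
- **Octree** — a single 3D tree over the power-of-two cube covering
  max(width, height, n_slices), subdividing into octants. Best suited to
  isotropic stacks; per-slice quadtrees are the 2D counterpart.

Making quadtrees per-slice (rather than one global structure per object) and
padding to a power of two are design choices: they keep subdivision
well-defined for arbitrary image extents and arbitrary 3D objects.

Memory is modelled in **abstract units**, not bytes: 3 units per pointlist
voxel (x, y, z) and 4 units per tree node (corner coordinates, size, state).
Concrete byte counts depend on language, word size and object headers, and
timing depends on hardware, so neither is asserted anywhere; the unit model
preserves the *orderings* that matter — pointlists win for single pixels and
thin skeletons (where subdivision must reach pixel scale anyway), quadtrees
win for large solid regions (for the benchmark ellipse, about 0.09× the
pointlist cost). Users with a fixed layout can recalibrate by scaling the two
constants in `imflow.coords`.

Exact laws used as test oracles: a single foreground pixel in a 2^k square
yields 4k+1 nodes and 3k+1 leaves (verified for k = 1..8 against a
brute-force subdivision oracle); a single voxel in a 64³ cube yields 49
octree nodes. For our generated one-pixel-wide strand the quadtree costs
about 5× the pointlist — the two methods stay within one order of magnitude
(unlike the 44× blow-up for the single pixel or the >10× win for the
ellipse), which is the behaviour the tests pin down; no fixed small-factor
bound is asserted because the exact ratio depends on how the strand threads
the subdivision grid.

Every store iterates voxels in (z, y, x) scan order regardless of internal
layout, which is what makes downstream measurements bit-identical across
methods (asserted in the tests as "store indifference").

## Object model and relationships

Objects are purely spatial (XYZ). Time and channel structure is expressed
only through relationships — a track is a coordinate-less object whose
children are per-frame detections. Two link flavours exist:

- **Parent-child**: at most one parent per parent class; multiple parents
  across classes; chains give grandparent relationships. Reassignment
  unlinks the previous parent first. Any assignment that would make an
  object its own ancestor (through any chain of classes) is rejected —
  the parent graph is acyclic at all times.
- **Partner**: symmetric, idempotent, many-to-many.

Both directions of every link are stored and kept consistent; removal of an
object (by filtering or workspace removal) severs all links on both sides.
Calibration lives on object sets and images; overlay rendering requires the
two to agree exactly, treating a mismatch as a hard error rather than a
silent unit mix-up.

Missing measurements are `None` in memory and empty cells in exports, never
0 or NaN text. Measurement-based filters retain objects with missing values
by default (`missing_policy="retain"`); dropping them is an explicit opt-in.

## Workflow engine

Execution is single-pass and linear. Effective enablement is computed by a
forward sweep: a module is effectively enabled iff its user flag is on and
every named input was produced (or updated in place) by an effectively
enabled earlier module and not removed since. This makes reactivity monotone
— enabling a module can only enable others. Structural validation (unknown
module ids, bad choice values, inputs no earlier module could produce) runs
before execution and is independent of enable flags, so a disabled producer
cascades as "effectively disabled" rather than erroring.

Workflow-handling modules evaluate predicates on object-set counts or image
measurements and either terminate the run (remaining modules marked skipped)
or skip forward to a later module labelled by nickname. Only forward jumps
are allowed. The predicate set (count / measurement, six comparators) is the
minimal one needed for empty-input guards and measurement gates.

Serialization is a versioned JSON dialect written with sorted keys and fixed
indentation, so serialize → deserialize → serialize is byte-identical. This
canonical form is embedded verbatim in every exported workbook, which is
what makes the provenance round trip testable as byte equality of re-run
exports. The original workflow format of GUI-based tools is not read; the
schema here is deliberately open and self-contained.

## Image modules

- Images are 5D `(t, z, c, y, x)` throughout; TIFF I/O uses ImageJ-style
  axis metadata, resolution tags for dx/dy, `spacing` for dz and
  `finterval` for the frame interval. Integer data round-trips exactly.
- Binary images are `{0, 255}` uint8.
- **Otsu thresholding** maximizes between-class variance over a 256-bin
  histogram spanning the data's min-max range (equivalent to min-max
  scaling before a fixed 256-level search); the variance maximization is
  delegated to scikit-image on that explicit histogram and is checked
  against an exhaustive search in the tests. A constant image yields an
  all-background result with a logged warning, not an exception. Foreground
  is strictly above the threshold, which makes thresholding idempotent on
  already-binary data.
- **Hole filling** is 2D, per slice and per timepoint (the conservative
  default; 3D filling would close vertical channels that are open in 3D).
- **Overlays** colour boundary pixels — foreground voxels with at least one
  in-slice 4-neighbour outside the object — using a seeded shuffle of an
  HSV wheel, so object colours are distinct and reruns with one seed are
  pixel-identical.

## Object modules

- **Identification** is connected-component labelling per timepoint
  (in-plane 4/8-connectivity; 6/26 in 3D), ids sequential in scan order.
- **Tracking** solves, per consecutive frame pair, the augmented linear
  assignment problem over squared calibrated centroid distances. Links
  beyond `max_linking_distance` are inadmissible; each object may instead
  take a "no link" alternative costed at 1.05× the largest admissible link
  cost (the convention of the standard particle-linking formulation). The
  completion block of the augmented matrix is free at transposed admissible
  positions, so the solver's objective is exactly (sum of link costs) +
  alternative × (number unlinked) — the tests verify optimality against an
  exhaustive enumeration oracle. Gap closing, track splitting and merging
  are out of scope. Every detection gets exactly one track parent; objects
  with no admissible link start new tracks.
- **Motion statistics** per track: path length (sum of calibrated step
  lengths), displacement (first to last), directionality = displacement /
  path length (in [0, 1]; missing when the path length is zero), mean
  velocity = path length / elapsed time, duration in frames, plus
  per-detection instantaneous step speeds. "Velocity" here is mean speed
  along the path; the directionality measure is declared, not claimed
  identical to any other tool's.
- **Skeleton decomposition** thins the mask (2D, per slice), marks skeleton
  pixels with more than two 8-neighbours as junction pixels, merges
  8-adjacent junction pixels into single junction objects, groups the rest
  into edges, and partners an edge with a junction iff any of their pixels
  are 8-adjacent. Terminal-branch pruning removes edges with exactly one
  junction partner; zero-partner edges (isolated lines, loops) and
  two-partner edges survive. Merging adjacent junction pixels is a choice —
  with the >2-neighbour rule, the pixels around a crossing all qualify, and
  one crossing should be one junction.

## Synthetic data

The generators are pure functions of their parameters and seed and return
ground truth alongside the image:

- `make_blob_image`: non-overlapping bright disks (intensity 200) on a dark
  background (20) with Gaussian noise σ = 5 — far below half the contrast,
  so the threshold truth is unambiguous and segmented areas equal the drawn
  areas exactly. `extra_radii` appends e.g. one deliberately tiny blob for
  size-filter tests.
- `make_moving_spots`: solid-disk spots whose integer centroids advance at
  constant velocity (default (3, 4) px/frame, a 3-4-5 triangle, so path
  lengths are exact by construction); tracks sit on parallel lines spaced
  more than 4× the per-frame step (plus 3σ at nonzero jitter), making the
  true linking unambiguous. Violated spacing raises rather than generating
  ambiguous truth.
- `make_skeleton_image`: axis-aligned one-pixel polylines (line, plus, H,
  grid) with junction/edge counts known by construction.
- `make_morphology_trio`: a single pixel, a meandering one-pixel random-walk
  strand, and a large solid ellipse in a 256² frame — the three morphology
  classes that separate the coordinate-store cost regimes.

What the generators do **not** emulate: point-spread functions, shot noise,
intensity gradients, touching or overlapping objects, anisotropic blur.
Passing tests therefore demonstrate the correctness of the bookkeeping and
the algorithms under unambiguous conditions, not segmentation robustness on
real microscopy data — thresholds, filters and linking distances always need
tuning per dataset.

Problem sizes in the tests and the acceptance script (200 equivalence masks
of 16-128 px per side and 1-8 slices, 50 tracking seeds with 2-5 spots over
5-10 frames, 1000-operation relationship audits, 100 random workflows,
3-job batches) were chosen as the smallest sizes that still exercise every
code path and regime boundary.

## Numerical and tie-break conventions

- Sample standard deviation uses the n−1 denominator; it is missing for
  single observations.
- Assignment ties are resolved deterministically by the LAP solver's
  first-minimum convention over matrices built in id order.
- Store iteration order, export column order (metadata, id, timepoint,
  measurements sorted by name, relationships sorted by class) and job
  discovery order (lexicographic) are all fixed so repeated runs diff
  cleanly; exported workbooks carry fixed document timestamps.
- Seeds: every stochastic module takes an explicit seed parameter
  (default 42); the CLI's `--seed` supplies the default for modules that
  leave theirs unset.

## Known limitations

- TIFF only; no proprietary/multiseries formats (the `series_name` metadata
  and filter hook exist so such readers could slot in).
- Tracking has no gap closing, splitting or merging; skeletons are 2D.
- No intensity/texture measurements; shape measurements are voxel-count,
  centroid and bounding-box based.
- Images are held fully in memory; there is no disk-backed storage tier.
- `skip_to` only jumps forward; there is no branching execution graph.
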