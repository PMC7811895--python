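# Methods

## Pipeline overview

The package computes, in order: (1) a connectome from a tractogram plus an
integer gray-matter label volume — each streamline whose endpoints map to
two distinct node labels contributes one count to that edge; (2) the
per-voxel edge-count field S_ij(x, y, z), incrementing an edge's count once
in every voxel the streamline traverses; (3) multi-layer labels — per voxel,
edges ranked by decreasing confidence P_ij = S_ij / TD; and (4) the region
query, which aggregates P over a mask weighted by track density. Because
Σ_region P_ij(v)·TD(v) = Σ_region S_ij(v), the layered query is
algebraically identical to direct summation of streamline counts whenever
no voxel's edge list was truncated by the layer limit; the package ships
both routes and the tests assert their equivalence.

## Coordinate conventions

All streamline points live in world millimetres; voxel indices arise only
through a grid affine. Voxel (i, j, k) is the half-open cube
[i−0.5, i+0.5)×… in voxel coordinates, with boundary points assigned to the
larger index. This must be pinned down explicitly: TCK files store world mm
while TRK files store a voxel-mm space resolved through their header, and an
unstated convention is how half-voxel shifts creep in. Mismatched grids
(mask vs. label volumes) are a hard error rather than a silent resample —
nearest-neighbour resampling of a significance mask changes which voxels are
in the region, which is a decision for the user's registration pipeline, not
for this tool.

## Voxel traversal

Traversal is exact: each polyline segment is intersected with the
half-integer boundary planes analytically, sub-intervals between crossings
are binned by their midpoints, and each vertex's containing voxel is added
(covering single-point streamlines and degenerate touches). No resampling
step size is involved, so there is nothing to tune. The test oracle is an
independent dense resampling of each segment (1% of the smallest voxel size)
with adaptive bisection wherever consecutive samples change voxel; since
voxels are convex, a straight subsegment whose ends share a voxel lies
entirely within it, making the oracle exact down to ~1e-9 voxel units of
chord length. Uniform sampling alone is not a valid equality oracle: corner
cuts shorter than the sampling step occur at a low but non-negligible rate
on random geometry, and the refinement is what makes the comparison strict
set equality rather than approximate.

## Endpoint assignment

By default a streamline endpoint takes the label of its containing voxel
(radius 0). Tractograms produced with anatomical constraints terminate
inside gray matter, but that cannot be assumed for arbitrary inputs, so a
radius search is an explicit option: an endpoint in background takes the
label of the nearest labeled voxel centre within `radius_mm` (world
distance, KD-tree; ties at equal distance go to the smallest node id).
Streamlines with an unlabeled endpoint or with both endpoints on the same
label (self-connections) are excluded from the connectome entirely.

## Multi-layer labels

Edges are coded as `i·1000 + j` (i < j ≤ 999), human-readable and roomy
enough for fine parcellations; 0 means "no label". Layer ordering ties are
broken lexicographically by (i, j), applied to the integer streamline
counts before any division so the tie-break is immune to floating-point
rounding. Confidences are stored as float32 (the on-disk 4D NIfTI
precision); tests use 1e-6 tolerances accordingly. The default depth of 60
layers is a parameter, not a constant: it is far more than the number of
edges through a typical voxel, and on the shipped phantom no voxel is
truncated, so build-time truncation and query-time truncation coincide.
When a voxel does exceed the depth, the kept layers are the largest-P edges
and their confidences sum to < 1.

## The region query

Any nonzero mask voxel is in the region; TD = 0 voxels contribute to
neither numerator nor denominator. The denominator is the full track
density, *including* mass whose labels were truncated out of the stored
layers: this makes Σ P_region ≤ 1 with equality exactly when nothing was
truncated, so the reported total is a coverage diagnostic (the CLI warns
when it falls below 1). Reported probabilities are not renormalized over
the reported labels — renormalizing would silently inflate survivors after
truncation. Disjoint clusters may be queried separately or as one combined
mask; the sums are additive, so the combined result equals the result on
the union.

## Group connectivity

For lobar-style probability maps, each edge's count is attributed once per
distinct group among its two endpoints — an edge within one group is not
double-counted, and per-group probabilities are each at most 1. The
`ignore_groups` argument lets the caller map nodes (typically the seed
structure being parcellated, e.g. a thalamus) to a group that is excluded
from the output maps and from the winner-take-all competition; without such
an exclusion the seed, touching every edge of interest, would trivially win
every voxel. Winner-take-all ties go to the smallest group id and
untraversed voxels get 0.

## Correspondence metrics

OL = |C∩R|/|R| (recall of the reference) and OR = |C\R|/|C|
(candidate-relative). The candidate-relative overreach is the only
convention under which 1−OR is a precision and the F1 formula is confined
to [0, 1]; with reference-relative overreach OR can exceed 1 and the
formula can go negative. Under this convention F1 equals the Dice
coefficient for all non-empty sets, which the tests assert numerically.
F1 is defined as 0 in the degenerate OL = 0, OR = 1 case. TDI Pearson
correlation is computed over the union of nonzero voxels by default —
including the vast zero background would inflate r arbitrarily — and is
reported as undefined (None), never a number, when variance vanishes.

## Phantom generator

The generator emulates only the geometry the pipeline consumes: rectangular
gray-matter blobs and tube-like bundles (straight or single-waypoint
quadratic arcs) with a per-streamline lateral Gaussian offset, tapered to
zero at the endpoints so every endpoint stays strictly inside its blob.
Paths are sampled at no more than half the smallest voxel size (the sample
count is sized from the control-polygon length plus the taper's π·|offset|
arc bound), mirroring 1 mm stepping on a 1 mm grid. It does not emulate
diffusion signal, curving anatomy, premature terminations, spurious
streamlines, or partial-volume effects — so passing tests demonstrate the
correctness of counting, layering, aggregation and ranking, not robustness
to tractography errors in real data.

The canonical crossing phantom (fixed seed 20201016) is a 20×20×20, 1 mm
grid with four 4³-voxel corner blobs, a 30-streamline bundle (nodes 1–2)
and a 10-streamline bundle (nodes 3–4) crossing centrally. Endpoints sample
the central quarter of each blob (endpoint_spread 0.25) with 0.4 mm jitter,
giving coherent tubes whose crossing voxels see both edges at close to the
generating 3:1 ratio; the measured top-edge region probability is ≈0.71
against the ideal 0.75, the gap coming from jitter and from the selection
of crossing voxels (which requires at least one streamline of the sparser
bundle, over-representing it). The ground-truth tolerance used in tests is
±0.1 around 0.75 to cover exactly this sampling geometry.

## Problem sizes

Tests and the acceptance script run entirely on generated data: the
canonical phantom (40 streamlines, 8000 voxels), 1000 random streamlines
over random anisotropic affines for the traversal cross-check, 50 random
masks for query-route equivalence, and 1000 random set pairs for the
F1/Dice identity. These sizes give exact or near-exact agreement checks at
interactive runtimes while exercising every code path.

## Known limitations

- Connectivity output is only as good as the input tractogram; the tool
  counts and aggregates, it does not correct tractography biases.
- Node ids are limited to 999 by the edge-code scheme.
- No image registration or resampling: all inputs must share one grid.
- The 4D label encoding is self-defined (documented above); no
  byte-compatibility with any externally distributed label resources is
  claimed.
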