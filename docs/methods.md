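# Methods

This note documents the models, conventions and numerical choices behind
`lipovoid`, in the order the pipeline runs them.

## Coordinates, units and containers

Volumes are `(nz, ny, nx)` arrays with slice index `z` ascending.  Voxels
are isotropic; anisotropic input is rejected.  The physical position of
voxel index `i` along any axis is `(i + 0.5) · voxel_size_um`
(voxel-center convention), which makes ball geometry unambiguous.  The
default voxel size of 16 µm/voxel sits mid-range for laboratory micro-CT
of centimetre-scale fat samples (≈ 15–18 µm/pixel).  Binary masks mark
void as true and serialize as 0/255 8-bit TIFF/raw for viewer
compatibility; all supported formats round-trip bit-exactly, and network
tables print floats at `%.17g` so re-reading reproduces every field
exactly.

## Synthetic phantoms

The generators are pure functions of their spec (seed included) and emit a
ground-truth mask, a feature log, and an exact void-fraction recount.  A
voxel is void iff its centre lies inside the continuous feature (closed
surface); the volume border counts as solid everywhere, matching the
extractor's boundary convention.

**Bubbles** emulate air entrained during shear crystallization: spheres
with lognormal radii (default median 48 µm, σ = 0.35, i.e. a few voxels at
16 µm — the size class of observed spherical pores) placed by rejection
sampling at uniformly proposed interior centres.  Default policy forbids
overlap and keeps a 2-voxel surface gap, so the logged bubble count is an
exact pore-count ground truth; an `allow` mode exists for stress tests.
Interior placement (centres at least one radius from the border) keeps
digitized bubble volumes exact; at the default target void fraction of
0.11 packing is far below the jamming limit and terminates quickly.

**Cracks** emulate sheet-like voids: unions of planar slabs (default 3,
random orientation, full extent) whose aperture varies in-plane.  The
aperture field is a smoothed Gaussian noise field rank-normalized to a
uniform distribution and mapped to `[0.1, 1] × 64 µm`, giving wide pockets
linked through narrow pinches — the structure a network extractor resolves
into pores and throats, as a real crack of varying opening does.
Deterministic axis-aligned uniform-thickness slabs are available for
analytically exact fixtures.  The paper-scale regime these defaults target
is `v ≈ 0.05` with connectivity well above 1 and components spanning the
volume; crack geometry statistics beyond that regime are not constrained
by available observations, so the defaults are calibrated to the regime
only.

**Sintered voids** emulate the space opened between crystal aggregates:
a smoothed seeded Gaussian field `G` is interpreted as an aggregate
domain field, and the void is its near-zero interface sheet `|G| ≤ t` —
an irregular percolating labyrinth.  The threshold `t` is the order
statistic that realizes the target void fraction exactly (to one voxel),
so no calibration loop exists.  The correlation length default (46 µm)
was calibrated once so that at `v = 0.12` the extracted connectivity lies
in the observed sintered-void range (`z ≈ 1.7–2.9` across seeds).  A
plain level-set void (`G ≤ t`) was rejected: at these fractions it sits
below the level-set percolation threshold and produces disconnected
blobs with `z < 1`, contradicting the morphology it is meant to emulate.

**Rendering** assigns a mode intensity per phase (defaults 180 solid / 60
void — air attenuates less, so void is dark), adds seeded Gaussian
detector noise (σ = 10), then applies an isotropic Gaussian blur (σ = 1
voxel) representing the point-spread/reconstruction smoothing, and clips
to 8-bit.  Noise precedes blur deliberately: smoothing acts on the noisy
signal as in a real reconstruction, so the blur also suppresses
voxel-wise noise.  With blur and noise both zero the rendering is exactly
two-valued and segmentation recovers the truth mask identically.

What the phantoms do **not** model: beam hardening, ring artifacts,
partial-volume sub-resolution porosity, non-Gaussian noise, and any
physically based crystallization dynamics.  Passing tests therefore
demonstrate correctness of the measurement chain on known geometry, not
robustness to every artifact of real scans.

## Segmentation

The histogram is built at 1 intensity unit per bin for integer volumes
(256 equal bins for real-valued), smoothed with a triangular kernel of
half-width 5 bins (overridable), and zero-padded at both ends so phase
modes at the histogram extremes are still detectable.  The two
highest-prominence local maxima are taken as the phase modes, with a
prominence floor of 0.1 % of the voxel count to ignore noise spikes; the
threshold is the minimum of the smoothed counts strictly between them,
with plateau ties resolved to the plateau midpoint.  Voxels on the void
side (`dark` by default) of the threshold become void, inclusively, so the
mask is monotone in the threshold.

A unimodal smoothed histogram raises an explicit "no valley" error
recommending the consensus method, which averages the valley threshold
(when defined) with the between-class-variance-maximizing (Otsu)
threshold.  This consensus is a declared stand-in for the unspecified
"combination of techniques" used in practice on low-contrast scans, and
results carry a `consensus` method flag.  Note the genuine failure mode it
addresses: void features only a few voxels across lose their intensity
mode to blurring, exactly the situation reported for fine-void samples.

## Maximal-ball network extraction

**Distance map.** The exact Euclidean distance transform of the void, with
a virtual solid shell outside the lattice (`scipy.ndimage`), measured
centre-to-centre.  The ball radius convention is the distance itself, with
no −0.5 surface correction; the constant offset cancels in comparisons and
is recorded in `extraction_params`.

**Maximal balls.** Every void voxel carries a candidate ball of radius
`d`.  For an exact distance transform, containment of ball `x` in ball
`y` (`|c_x − c_y| + r_x ≤ r_y + ε`, `ε = 1e−9` voxel) forces the
collinear equality `d(y) = d(x) + |x − y|` with `y` on the lattice ray
from `x`'s nearest solid point through `x`; if it holds for any such `y`
it holds for the first lattice point beyond `x` on that ray, and a voxel
with two or more tied nearest solid points can never be contained.
Redundancy removal is therefore a single vectorized ray-neighbour test,
verified exact against an O(n²) pairwise oracle in the test suite.

**Pores and regions.** Pore seeds are the 26-neighbourhood local maxima of
`d`, with each connected plateau of maxima collapsed to one seed (its
lexicographically smallest voxel) so digitized spheres do not over-seed.
Every void voxel is then assigned to exactly one pore by priority-flood
growth: voxels are claimed in decreasing `d`, each joining the region of
its highest-`d` already-assigned 26-neighbour (ties to the lower region
id).  Equal-`d` ties pop in insertion (FIFO) order, the standard
priority-flood watershed discipline, which keeps plateau partitions
front-driven and deterministic; on gradient-rich phantoms the assignment
agrees with an independent watershed implementation on ≈ 99 % of voxels,
the residual being plateau tie-breaks that no rule makes unique.

**Throats.** For each pair of 26-adjacent regions, the throat radius is
the maximum of `d` over the interface voxels — the saddle height, i.e. the
minimal inscribed ball along the connecting path.  One throat is recorded
per adjacent pore pair.  Dead-end contacts (a single region meeting the
border) are not throats, so isolated pores have coordination 0.  Throat
length is the pore centre distance minus both pore radii, clamped to one
voxel; throat volume uses the cylinder model `π r² L`.  Saddle-ball radius
(rather than a cylinder fit) is the throat radius definition and is
flagged in `extraction_params`.

**Merging.** A saddle nearly as high as the smaller adjacent peak is an
over-segmentation artifact (spurious ridge maxima of digitized bodies,
constant-radius neck plateaus), not a genuine constriction.  Pore pairs
with `saddle / min(peak)` above `merge_ratio` (default 0.7, exposed and
logged) are merged **sequentially, highest ratio first**, recomputing
saddles after each merge.  Sequential greedy merging is essential: merging
all super-threshold pairs simultaneously chains two genuinely distinct
pores together through an intermediate neck fragment (a dumbbell would
collapse to a single pore), whereas greedy merging absorbs the fragment
into one side and then correctly retains the neck as a throat.

**Invariants** maintained and asserted: pore voxel counts partition the
void exactly; Σ coordination = 2 × throats (hence `z = 2T/P`); throat
radius never exceeds either adjacent pore radius; extraction is
deterministic under the stated tie-breaks.  An optional
`min_pore_radius_um` filter drops small pores (and their throats) and
reduces the void count accordingly; it is off by default.

## Void metrics

Radii convert to µm per replicate before any averaging (replicates may
have different scan resolutions).  `R_43` weights pores by assigned-voxel
volume and throats by cylinder volume; a sphere/cylinder model-geometry
weighting variant is available where assigned volumes are not meaningful.
Radius distributions are volume-weighted into bins of width 5 µm centred
on multiples of 5 µm (nearest tick; half-way ties go up).  Micropores are
features with radius ≥ 10 µm, inclusive, counted by feature (a
volume-weighted variant is also provided); note this follows the source
field's usage, which is inverted relative to IUPAC nomenclature.
Replicate summaries are unweighted means with sample (n−1) standard
deviations, and replicate distributions average per-bin with absent bins
contributing zero.

## Group statistics

Groups are the cells of a per-base-fat factorial (emulsifier × shear
type); comparisons never cross base fats.  The Brown–Forsythe test
(Levene on deviations from group medians) gates the branch at p ≤ 0.05:
homoscedastic data get ordinary two-way ANOVA (type-II factor and
interaction p-values) with Tukey HSD pairwise comparisons across cells;
heteroscedastic data get Welch's ANOVA with Dunnett T3 pairwise
comparisons — Welch t statistics with Welch–Satterthwaite degrees of
freedom against Šidák-style studentized-maximum-modulus critical values,
the standard construction when only the test's name is specified.  A
design unbalanced by more than one replicate forces the Welch branch with
a recorded warning; zero variance everywhere short-circuits to a flagged
"no difference detectable" result instead of dividing by zero.  Letters
come from the insert-and-absorb compact-letter-display algorithm, so two
groups share a letter iff their pairwise p exceeds α (checked exhaustively
per result).

Calibration caveat: at the replicate counts typical of this kind of study
(n ≈ 3–5 per group) the median-centred Brown–Forsythe test is strongly
conservative — its empirical type-I error at n = 5, k = 4 is below 0.01
versus the nominal 0.05, a known small-sample property of the test (it is
well calibrated by n = 20, which the test suite verifies).  The practical
effect is a bias toward the ordinary-ANOVA branch for small samples.  Both
ANOVA branches themselves calibrate to nominal α within Monte-Carlo error.

## Pipeline and reproducibility

A run executes an ordered subset of simulate → segment → extract →
metrics → stats from a nested YAML config.  One global seed derives
per-stage substreams by hashing `seed:stage` (always below 2³¹); every
stage writes sidecar metadata; and the manifest lists each artifact with a
SHA-256 checksum.  Identical config and seed yield byte-identical
manifests; the run directory itself is not part of the configuration.
Stage isolation holds: running later stages from persisted intermediates
reproduces the single-run outputs byte-for-byte.  The ball-and-stick
export writes one record per pore (sphere) and throat (cylinder between
pore centres) with a colour scalar `log10(radius_um)`, ordered by id.

## Problem sizes

The test suite and acceptance script use phantoms from 16³ (oracle
comparisons) through 96³–100³ (morphology regimes, three replicates and
three seeds each) to 200³ (50-bubble count recovery); statistical
calibrations use 1000-repeat null simulations at n = 5 per group.  These
sizes were chosen so the full verification cycle completes in a few
minutes on a single CPU while every oracle remains exhaustive at its
scale.

## Known limitations

Throat radii come from interface saddles, which digitization can bias
upward by a fraction of a voxel (the dumbbell fixture recovers a radius-3
neck as √10 ≈ 3.16).  Whether multiple distinct throats between the same
pore pair should be counted separately is unknowable from the available
description; this implementation records one per adjacent pair after
merging.  Valley segmentation degrades to the consensus fallback when
void features are only a few voxels across; both estimates are reported
in the diagnostics.  The extractor is not intended to replicate any
specific third-party extraction code's outputs, only the documented
maximal-ball behaviour.
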