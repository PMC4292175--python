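# Methods

This note records the models, conventions and parameter choices behind
`tomopack`, and what its synthetic benchmarks do and do not establish
about real tomographic data.

## Coordinates and containers

Volumes are `grid[ix, iy, iz]` arrays with an isotropic voxel size in
nm; the physical origin is the corner of the first voxel and voxel *i*
is centred at (*i* + 0.5)·voxel. All rotations are proper (det +1) and
exchanged on disk as intrinsic ZYZ Euler angles in degrees. Volumes are
written as MRC2014 mode-2 files by a minimal reader/writer in
`core.py`; voxel size travels in the header cell fields, origin in the
origin fields, x fastest on disk.

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes —
quasi-spherical ~13 nm particles at close-packed density — not the
physics of image formation.

- **Lattices.** HCP is built from A/B triangular layers at the ideal
  axial ratio c/a = √(8/3); CCP as FCC; BCC as the conventional cell;
  all scaled so the nearest-neighbor distance equals the sphere
  diameter (hard spheres touch). One lattice point is anchored at the
  box centre, the whole lattice rotated by the scene orientation.
  HCP's two basis sites have 60°-rotated coordination environments
  (HCP is not a Bravais lattice); the generator records a per-particle
  orientation including this twist, so ground-truth alignment
  rotations (`SyntheticScene.alignment_transforms`) exist for recovery
  tests.
- **Jitter.** Isotropic Gaussian displacement per particle, independent
  across particles — the minimal, parameter-recoverable noise model for
  positional disorder. Jittered particles leaving the box are dropped
  so scene invariants (all positions inside the extent) hold.
- **RANDOM control.** Uniform hard-sphere rejection sampling at 30%
  packing fraction (random sequential addition saturates near 38%, so
  placement reliably succeeds), with a 10⁴ retry bound per particle.
  This provides the disordered negative control for lattice detection.
- **Rendering.** Each particle is a cosine-tapered solid sphere; the
  one-voxel taper straddles the nominal radius so the integrated
  density matches the analytic sphere volume to second order. Additive
  i.i.d. Gaussian noise; "SNR 1" in the tests means noise SD equal to
  the particle amplitude. The optional missing wedge is a binary
  Fourier mask for a ±60° single-axis tilt (y tilt axis, z beam axis),
  applied before noise. No CTF, dose, or lamella geometry is simulated:
  the matching template is itself a sphere, so soft spheres are the
  appropriate level of realism for testing the localization contract.
- **Membrane stacks.** A piecewise-constant intensity profile
  (membrane, lumen, membrane, interthylakoid gap per thylakoid; gaps
  only between thylakoids; stroma margins at both ends) rendered with
  area-weighted anti-aliasing. Default widths 4.9 / 9.0 / 3.6 nm give
  the 22.4 nm lateral repeat; default levels put the lumen brightest
  (least dense), membranes darkest, gap at stroma level.
- **Invagination fixtures.** Records (projection size *i*, envelope
  width *m*, 3D tip distance) drawn from caller-supplied
  distributions. Geometry is consumed as annotated records because the
  upstream measurement in practice comes from manual segmentation;
  the implementable content is the counting rule and the statistics.

## Template matching

Localization is rotation-free by design: a spherical template makes
the orientational search redundant. The correlation is *locally*
normalized — per-position mean and SD under a binary spherical mask —
because a dense particle matrix has an uneven background and only
local normalization makes scores comparable across the volume.
Degenerate positions (vanishing local variance) score 0; positions
whose mask crosses the volume boundary score −1 rather than being
padded, since thin lamella-style volumes make padded correlations
systematically biased. Scores are clipped to [−1, 1].

The low-pass cutoff uses the Crowther relation d = π·D/N with
N = 180°/increment (projections spanning a half-turn). At a 2°
increment and D = 12 nm this nominal cutoff (0.42 nm) is finer than
the Nyquist spacing of any realistic tomogram voxel, so the cutoff is
clamped at 2·voxel when applied; the filter edge is a raised cosine
three Fourier voxels wide, leaving DC (and hence the mean) untouched.

Peak extraction is greedy and exhaustive: take the global maximum,
silence a sphere of the exclusion radius (default: the template
radius, 6.84 nm — hard spheres cannot approach closer), repeat until
the score floor or the peak budget is reached.

## Subtomogram averaging

Boxes (default edge 45.6 nm, read as a cube of that edge) are cut from
the *unfiltered* volume — the low-pass exists only for matching.
Alignment is an exhaustive intrinsic-ZYZ grid search (deduplicated at
the gimbal degeneracies, lexicographic order fixing tie-breaks) with
the translation solved per rotation by FFT cross-correlation
restricted to a shift ball; scoring uses masked, mean-subtracted
correlation under a soft spherical mask, normalized at zero shift.
Internally each grid rotation is applied once to the *reference* and
reused against every box (the correlation of ref with a rotated box
equals the correlation of the inversely rotated reference with the
box, with the shift rotated accordingly), which makes the grid search
linear rather than quadratic in volume resamplings. Rotated volumes
are resampled trilinearly about the box centre.

The default schedule is coarse-to-fine (30°, 30°, 15°, 7.5°); the
iteration-0 reference is the unaligned mean and no symmetry is imposed
at any stage. The returned transforms are exactly those applied to
build the final average (re-applying them reproduces it). A drop in
mean score logs a warning rather than raising. Missing-wedge
compensation in the alignment score is deliberately omitted: for
quasi-spherical particles found by a spherical template the wedge bias
is second order, and the synthetic benchmarks run without a wedge.
A block-binning helper supports the standard practice of aligning at
2× binning when only the rotations are needed downstream.

FSC is computed over shells one Fourier voxel wide from the first
non-DC shell to Nyquist; resolution at a threshold is found by linear
interpolation in frequency, a shell exactly at the threshold counts as
the crossing, and a curve that never crosses reports the Nyquist
spacing with a flag.

## Neighbor clouds and clustering

The range query is a closed ball (offsets at exactly the radius are
kept), default radius 22.8 nm, and never includes the reference's own
zero offset. Pooling applies each reference's alignment *rotation* to
its offsets — translations are irrelevant because offsets are already
reference-centred — and by default adds one zero offset per reference
(`include_self`), which guarantees the origin cluster of the k = 13
model (reference plus 12 contact neighbors). The flag exists because
the alternative reading (origin cluster from symmetry alone) is
defensible; both modes are exercised in tests.

At ~15 nm spacing the 22.8 nm ball also admits the second shell at
√2·d ≈ 21.3 nm. The default pipeline keeps those points (k-means with
k = 13 still isolates the origin cluster); for clean parameter
recovery two pre-filters are provided: a per-reference 12-nearest cap,
and a contact filter that estimates the contact distance robustly over
all references (median of per-reference median nearest-offset norms)
and cuts at 1.2× that estimate — near the midpoint between shells, so
that positional noise trims almost none of the first shell's far tail.
A per-reference minimum-based cut was rejected because the minimum of
twelve noisy distances is biased low, which propagates into fitted
diameters.

k-means uses scikit-learn's implementation (squared-Euclidean
objective, k-means++ greedy seeding, best of 10 restarts), which is
deterministic under the seed — the contract that matters; its
objective is verified against exhaustive assignment enumeration on a
small instance. Centers are returned sorted by distance from the
origin.

## Hard-sphere lattice fitting

Cluster centers live in the subtomogram average's frame, which has no
relation to lattice axes, so registration precedes RMSD: a 15° Euler
grid of starts, each refined by iterative closest correspondence
(assign each data point to its nearest model point — model points
reusable, matching "nearest point correspondences" and robust when
data are fewer than model points — then re-solve the rotation by SVD
projected to det +1, iterate to assignment stability). Only proper
rotations are searched; the HCP enantiomorph is handled by also
registering the z-mirrored model set and reporting the better fit as
the same model.

The diameter scan (default 10–20 nm, 0.05 nm steps, 0.01 nm refinement
around the coarse arg-min) exploits continuity: the full rotation grid
runs at the first diameter only, and subsequent diameters warm-start
from the best rotations found so far. HCP's axial ratio is fixed at
the ideal √(8/3) — these are hard-sphere models, not free lattices. An
arg-min at the scan boundary is flagged. Model selection returns the
model with the smallest minimal RMSD and keeps every per-model curve;
ties within 10⁻⁹ are reported as ambiguous. The fit operates on the
13 cluster centers by default (the alternative — fitting the full
cloud — is possible via the within-radius model neighborhood mode).

## Morphometrics

The lateral repeat comes from the lag-wise Pearson autocorrelation of
the profile (each lag's coefficient is the correlation of the
overlapping segments, immune to finite-window amplitude tilt), taking
the earliest local maximum within 80% of the strongest — a guard
against intra-period coincidence sub-peaks of the
membrane/lumen/membrane/gap motif — refined by parabolic
interpolation; a best peak below 0.2 raises a no-periodicity error.
Membrane troughs are segmented as runs below a threshold 30% up the
dynamic range (flat-bottomed troughs defeat peak finders), and every
layer boundary is the interpolated half-maximum crossing between the
trough level and the *adjacent local* plateau level (median of
above-threshold samples between troughs) — local referencing keeps
the estimate robust to intensity gradients. Interior plateaus are
classified lumen vs gap by thresholding at the midpoint of the
plateau-level range, with an alternating fallback for degenerate
profiles. Widths are averaged over repeats; the additivity identity
2·membrane + lumen + gap = repeat holds within 0.5 nm on all synthetic
fixtures and serves as an internal consistency check.

Averaged line scans sample trilinearly along the scan line, averaging
across a disc of parallel lines (or across the single in-plane
perpendicular for effectively-2D volumes); the central line must stay
inside the volume, offset lines are edge-clamped. Invagination
statistics implement the counting rule (counted iff *i* > *m*),
density per area over counted records, and cumulative tip-distance
fractions at 40 and 100 nm; all outputs are permutation-invariant in
the record list.

## Problem sizes in the test suite

The end-to-end benchmark uses a 110³ nm scene (575 particles before
boundary effects; ≥ 200 required) at 1.14 nm voxels, 5% positional
jitter and SNR 1, matched at full resolution and averaged at 2×
binning on a 45°/45° schedule — sizes chosen so the whole suite runs
comfortably on a single desktop core while leaving the recovery margin
(two coarse scan steps, 0.1 nm) intact. Registration-heavy tests use
the vectorised batched ICP, so full 15° grids over SO(3) remain cheap.

## What the benchmarks show — and what they do not

Passing tests establish that the implementation recovers its own
generative truth: localization recall on soft spheres, alignment
recovery of grid rotations, collapse of polycrystalline neighbor
clouds under correct rotations, and model/diameter recovery through
the full chain. They do not calibrate the generator to any real
dataset: no noise or jitter statistics for a real particle matrix are
published, CTF and missing-wedge effects on scores are not modelled in
the benchmarks, and data-bound quantities (numbers of subvolumes,
achieved FSC resolutions, absolute RMSD values on real clouds) depend
on tomograms that are not available. The disordered negative control
bounds the false-positive behaviour of model selection only under the
generator's conditions.

## Known limitations

- Alignment assumes the particle (plus local neighborhood) dominates
  the box; strongly overlapping neighbor shells at very coarse angular
  steps can lock subsets into symmetry-related frames when the stack
  is tiny.
- The FSC is unmasked and single-map (no gold-standard half-set
  protocol beyond index-parity splitting in tests).
- `measure_layers` expects stacks whose membranes are the darkest
  (or, with `polarity="bright"`, brightest) extreme and at least two
  repeats.
- The k = 13 clustering presumes near-complete first shells; heavily
  truncated boundary neighborhoods should be pre-filtered or excluded
  by the caller.
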