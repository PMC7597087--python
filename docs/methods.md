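# Methods

## The automaton

`bandgrowcut` implements seeded cellular-automaton segmentation in the
GrowCut family.  The automaton lives on the pixel/voxel lattice of the
image; each cell carries a triplet *(λ, σ, C)*: a region label λ (0 while
unlabelled), a strength σ ∈ [0, 1] expressing confidence in that label,
and a fixed feature C, the grey intensity normalised to [0, 1].  Seed
cells start with their region label and σ = 1; everything else starts
unlabelled with σ = 0.

At every synchronous step, each neighbour *q* of a cell *p* attacks with
force

    g(|C(p) − C(q)|) · σ(q),      g(x) = 1 − x,

and *p* is captured — λ(p) ← λ(q), σ(p) ← attack force — whenever the
force strictly exceeds σ(p).  All updates in a step read the previous
state (fully synchronous semantics).  The linear attenuation g is the
classical choice: it is non-increasing, maps identical features to full
strength transfer and maximally different features to none, and, with
σ ≤ 1, keeps every strength inside [0, 1] for the whole run.  Because no
attack force can exceed 1, seed cells are never overrun.

The band-based variant (BBG) adds, per cell and per iteration, *k* remote
neighbours drawn uniformly without replacement from a Chebyshev annulus
at distance *a..b* (clipped to the grid).  A sampled remote attacker
captures only if it is strictly stronger than both the defence and the
best local attacker — local neighbours win ties.  Every capture is
classified as a *local win*, a *remote win* (no local attacker would have
succeeded), or a *remote override* (a weaker local capture was preempted);
the cumulative counts are reported with every result.

## Band geometry

The band is implemented as the inclusive Chebyshev annulus
a ≤ d∞ ≤ b, which degenerates to the Moore shell for a = b and composes
(band 1..r equals Moore radius r).  Two closed-form cell counts are
exposed deliberately:

* `band_count(a,b,d) = (2b+1)^d − (2a−1)^d` — the inclusive annulus this
  package actually samples from;
* `eq5_count(a,b,d) = (2b+1)^d − (2a+1)^d` — the count conventionally
  quoted for band neighbourhoods in the CA literature, which corresponds
  to the half-open annulus a < d∞ ≤ b.

They differ by the inner shell, `(2a+1)^d − (2a−1)^d`; the test suite
asserts both against brute-force enumeration of their respective
membership predicates rather than hiding the discrepancy.  A literal
"corner blocks" reading (per-axis bounds a ≤ |Δ| ≤ b on every axis) is
available behind `band_geometry="corner"` for comparison.

Boundaries clip (no wrap-around).  Enumeration is in row-major offset
order (slice-major first in 3D), which pins down the deterministic
tie-break: among equally strong local attackers the first in enumeration
order wins.

## Parameters

| parameter        | default | meaning                                              |
|------------------|---------|------------------------------------------------------|
| standard_kind    | moore   | local neighbourhood family                           |
| standard_radius  | 1       | local radius r                                       |
| remote_band      | none    | (a, b) annulus radii; none = classical GrowCut       |
| k                | 5       | remote neighbours sampled per cell per iteration     |
| max_iterations   | 2000    | cap; non-converged runs are returned as-is           |
| seed              | 0      | RNG seed; runs are bit-reproducible given it         |
| seed fraction    | 0.75    | vertical seeds trimmed to this fraction of the run   |

k = 5 and the 2000-iteration cap follow standard practice for this
algorithm family; the studied band placements are (2,5), (5,10), (10,30)
and (30,45) with a Moore r=1 local neighbourhood.

Convergence is declared after the first iteration with zero captures.
Under stochastic resampling a later draw could in principle still
succeed; stopping at the first quiet iteration keeps runs finite and
matches the usual converged-or-capped reporting.  Same-label recaptures
with a strictly stronger force are allowed (a strength refresh) — the
transition rule is label-agnostic.

## Seeding

To avoid hand-placed scribbles, seeds are generated from a ground-truth
mask: for each region (background, foreground) the tallest contiguous
vertical run of that region inside a single column is selected, trimmed
to `max(1, floor(0.75·h))` pixels, and centred within the run (slack
split floor/ceil).  Ties among equally tall runs go to the leftmost
column, then the topmost run.  "Tallest" is measured over contiguous runs
— a seed is a line of pixels — not over column totals.  For 3D stitch
mode, seeds are generated per slice; slices missing a region get no seed
for it and fully unseeded slices are returned unlabelled with a warning.

## Metrics

Overlap scores use the standard confusion-count definitions; Dice equals
both 2J/(1+J) and the harmonic mean of precision and recall, and both
identities are asserted on random masks.  Degenerate conventions: both
foregrounds empty → all scores 1; one side empty → 0.

Over- and under-segmentation entropy are the two conditional entropies of
the joint label distribution P(T, S) (ground truth T, prediction S):
OSE = H(S|T) and USE = H(T|S), natural logarithms, 0·log 0 dropped.
Their sum is the variation of information; mutual information is
H(S)+H(T)−H(S,T) and is cross-checked against scikit-learn in the tests.
Only ratios of OSE/USE are typically compared, so the log base cancels
there.

Unsupervised homogeneity: foreground/background error are unnormalised
sums of squared deviation from the region mean intensity; uniformity is
their convex combination weighted by region pixel proportions;
discrepancy is the squared error between the image and its
per-region-mean reconstruction, which for binary segmentations equals
fg_error + bg_error (asserted).  Hausdorff distances operate on boundary
pixels — foreground pixels with a 4-neighbour (or image border)
background — under the Euclidean metric; the average variant reports the
mean of the two mean directed distances.  Empty foregrounds raise
`EmptyForegroundError` rather than returning a number.

## Synthetic scenes

The generator produces piecewise-constant two-region scenes (background
0.9, foreground 0.1 — the same high-contrast values as the four-pixel
worked example) with optional Gaussian and salt & pepper noise, clipped
to [0, 1].  Ground truths are binary and never perturbed by noise.
Scenes are reproducible from (spec, seed) alone.

The *disconnected scene* splits the foreground into a seeded and a
seedless component across a background gap of width w (default 5 on a
40×40 grid).  Classical GrowCut has no propagation path to the seedless
component; a band with b ≥ w+1 does, and the rescue then spreads locally
through the near-identical intensities.

The *study corpus* (10 scenes, 64×64) is designed to expose both
directions in which a remote band changes the output:

* a seedless 12×10 true-foreground component at a gap cycling over
  {6, 12, 22, 32} px — bands that bridge the gap rescue it, so mean USE
  falls as the band moves outward ((5,10) bridges gap 6; (10,30) bridges
  6/12/22; (30,45) all, directly or through chains of flipped blobs);
* five foreground-intensity clutter blobs that the ground truth marks
  background, at Chebyshev distances ≈ {3, 5, 10, 19, 36} from the true
  foreground with cumulative sizes ≈ {32, 41, 66, 102} px reachable by the
  four bands.  Classical GrowCut has no path to them; every band flips
  some, so mean OSE exceeds the classical value for all four placements.

The blob sizes were chosen by entropy arithmetic: a missed or flipped
region of m pixels contributes roughly P(marginal)·H(m/region) nats to
the respective conditional entropy, and the schedule above makes the
clutter term dominate OSE for every band while the rescue term dominates
USE for the far bands.  Noise is Gaussian (σ 0.03) on all scenes plus
salt & pepper (rate 0.01) on even-indexed scenes.

What the corpus does *not* emulate: textured regions, smooth intensity
gradients, anisotropic voxels, multi-label anatomy, or annotation noise.
Passing the corpus-level tests shows the band mechanics behave as
designed under controlled contrast and clutter; it does not certify
performance on natural or clinical images.

## Numerical and implementation choices

* Features are float64 in [0, 1]; integer images are divided by their
  dtype maximum on load (8/12/16-bit).
* Remote sampling is exact sequential without-replacement sampling over a
  precomputed per-cell table of in-grid band offsets (rank draws with
  duplicate rejection); it is distribution-identical to drawing from the
  clipped band with `numpy.random.Generator.choice` and is reproducible
  from the run seed.  Kernels (geometry only) are cached per
  (shape, neighbourhood).
* The per-cell table costs O(n_cells × band size) memory (tens of MB for
  a 64×64 image with the (30,45) band); very large images with very wide
  bands trade memory for the vectorised sampling.
* Stitch mode derives one child seed per slice from the run seed, so 3D
  results are reproducible and slices are independent.
* The engine's stochastic path can be replayed: `run` can log the drawn
  remote samples and an independent naive double-loop reference consumes
  the same samples in the tests, giving identical label evolution.

## Problem sizes used in the shipped experiments

The worked example is 1×4; oracle-equivalence runs use twenty 6×6 images;
rescue statistics use 50 seeded runs on the 40×40 disconnected scene; the
entropy-balance study uses the 10-scene 64×64 corpus across five
neighbourhood configurations.  These sizes make every experiment
reproducible on a laptop in minutes while leaving the mechanisms under
study clearly expressed.

## Known limitations

* All shipped experiments are foreground/background; the data model
  supports more labels but multi-label behaviour is untested.
* Convergence under resampling is declared at the first quiet iteration;
  a run reported "converged" could still accept a capture under a
  different future sample.
* Wide bands on large 3D volumes are memory-hungry (see above).
* The literal corner-block band geometry is provided for comparison only
  and is not exercised by the study corpus.
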