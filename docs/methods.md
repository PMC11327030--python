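# Methods

This note documents the models, estimators and numerical choices
behind `gelquant`, what the synthetic generators do and do not
emulate, and the known limitations.

## Trajectory statistics

**Model.** A track is a time-ordered sequence of positions in μm at a
fixed frame interval (default 10 min, 144 frames ≈ 24 h — typical
long-term live imaging of cells in 3D collagen).  Frame gaps from the
upstream tracker are kept as missing frames.

**Mean speed** averages step length over elapsed time for each pair of
consecutive *observed* frames, so a step spanning a k-frame gap is
divided by k·Δt rather than being treated as a single-frame jump.

**Static classification** compares total path length (the sum of step
lengths, not net displacement) with a threshold of 1.5 cell diameters
— 75 μm for the 50 μm diameter used in tracking.  The boundary is
strict: a cell moving exactly 75 μm counts as motile.  "Total
distance" is read as path length because the same protocol defines
persistence with "total displacement" as the path-length denominator.

**MSD and α.**  The MSD is time-averaged within each track:
MSD(ℓ) = mean over t of |r(t+ℓ) − r(t)|², using every pair of observed
frames exactly ℓ frames apart (pairs straddling a gap do not exist at
that lag).  Lags are restricted to 25% of the track length by default
— standard practice for short single-particle tracks, where long-lag
time averages are dominated by a handful of pairs — and lags with
fewer than 3 pairs are dropped.  α is the unweighted least-squares
slope of log MSD vs log lag; non-positive MSD values are excluded, and
tracks with fewer than 10 frames (or fewer than 3 usable lags) get
α = NaN rather than an exception, so cohort batches always complete.
α is fitted per cell and then averaged over the cohort; whether static
cells enter the speed average is a caller choice (they are included by
default), matching how migration tables typically mix both.

**Persistence** is net displacement over path length; a path of zero
length is assigned 0 (a cell that went nowhere maintained no
direction), resolving the 0/0 case.

**Calibration.**  On simulated 2D Brownian cohorts (200 tracks, 144
frames, lags 1–20) the mean fitted α is 1 within ±0.1; fractional
Brownian cohorts with H ∈ {0.15, 0.3, 0.45, 0.5, 0.75} recover
α = 2H within ±0.1 (500 tracks).  Both checks run in the test suite
and the second spans the subdiffusive range observed for confined
cells in dense collagen.

## Synthetic trajectory generators

- *Brownian*: i.i.d. Gaussian increments per axis; ensemble
  MSD(τ) = 2·d·σ²·τ exactly.
- *Fractional Brownian motion*: each coordinate is exact fBm obtained
  by Cholesky factorization of the covariance
  cov(s,t) = ½(s²ᴴ + t²ᴴ − |t−s|²ᴴ) at integer frame times.  At track
  lengths of a few hundred frames the factorization is cheap, and the
  construction has no spectral-approximation error; the factor is
  cached per (length, H).
- *Persistent walk*: constant step length (speed·Δt) with von Mises
  turning angles of concentration κ; κ = 0 is an uncorrelated walk,
  κ → ∞ ballistic (persistence → 1).  κ > 1e8 is treated as exactly
  ballistic to avoid degenerate von Mises sampling.

All generators draw from a single seeded `numpy.random.Generator` per
call (or one passed in for cohort builds), so identical seeds and
parameters give bit-identical output.

## Fiber fields and their analysis

**Rendering.**  Fibers are straight anti-aliased capsules (segment +
round caps) with centers uniform over the field, Gaussian lengths
truncated at > 0 by redraw, von Mises orientations, and a fixed width;
intensities add where fibers overlap and clip at saturation, emulating
SHG signal accumulation, with Gaussian read noise added last.
Density presets emulate 1/3/6 mg/mL collagen as more (40/150/500),
shorter (33/16/8 μm mean), thinner, less aligned (κ = 3/1/0.2) fibers
on a 256² field at 0.5 μm/pixel.  Only the *statistical signatures*
(density, length, orientation trends) are emulated — no fiber
curvature, cross-linking, 3D projection or depth attenuation — so
passing tests demonstrate estimator correctness, not realism of the
texture.

**Binarization** is Otsu per image or a fixed threshold applied
batch-wide (the consistency rule used when comparing conditions).  A
constant image yields an empty mask with a warning rather than an
arbitrary threshold.

**Fiber lengths** automate the manual ruler protocol: skeletonize the
mask, split the skeleton at junction pixels (≥ 3 neighbors), trace
each branch (1 per axial step, √2 per diagonal step, plus one pixel of
end extent), and sample 20 segments without replacement.  Crossing
fibers are split into branches, so sampled lengths underestimate true
fiber length in dense fields; the density *trend* is preserved, which
is what the comparison uses.

**Free-space length Lf** is the side of the largest axis-aligned
fiber-free square.  The deterministic mode is exact: feasibility is
monotone in the side length, so a binary search with an integral-image
emptiness check finds the maximum; it is verified against brute-force
enumeration over all placements in the tests.  The Monte-Carlo mode
accepts a side while randomly placed squares can still be empty;
under the default `any_empty` criterion it converges to the exact
value as draws grow.  A `modal` criterion (accept while zero is the
*modal* crossing count) is also provided; it settles at the smaller
scale where empty placements stop being typical, and is kept for
protocol fidelity rather than as the default.  Rotated squares are
out of scope.

**FFT metrics.**  The power spectrum is |FFT|² of the mean-subtracted,
Hann-windowed image (window off for Parseval checks).  The anisotropy
ellipse takes the power-weighted second moments of frequencies above
the 0.9 power quantile; retaining the full top decile keeps the
moment estimate stable enough that isotropic fields score close to 1
(mean ≈ 1.2 over seeds) while aligned fields score several-fold
higher.  The real-space fiber orientation is reported perpendicular
to the spectral major axis.  Pore and fiber size come from the
radially averaged profile: the dominant non-zero frequency f* sets a
characteristic spacing 1/f*, split into fiber width
(spacing × SHG-positive area fraction) and pore size (the remainder)
— the simplest decomposition that is verifiable on analytic stripe
patterns (period 10 px, 30% duty → 3 μm fiber, 7 μm pore).  A profile
whose maximum is below 5× its median (pure noise) is reported
undefined.  This scheme is one of several defensible readings of
"pore and fiber size from the power plot"; it is chosen for
testability.

## 3D morphometry

**Segmentation.**  "HK-means" is realized as hierarchical 1D k-means
on the intensity histogram: starting from one class, the split that
most reduces the within-class sum of squares (found exhaustively over
the 256 histogram bins, hence deterministic) is applied until 3
classes exist; the brightest class is foreground and components below
the minimum region size (default 10,000 voxels, scaled down for small
phantoms) are removed.  Per-channel masks are hole-filled, unioned,
and the largest component kept — the membrane channel outlines the
cell, the nucleus channel covers the inside, so the union fills to a
solid.

**Volume** is voxel count × voxel volume.  On noiseless ellipsoid
phantoms the error is < 5% at 1 μm voxels and at least halves when
the voxel edge halves.

**Axes.**  The longitudinal axis is the 3D Feret diameter ("between
the furthest points"); the transverse axis is the widest caliper
perpendicular to it — the only rotation-invariant reading of
"transversal distance between the furthest points".  Widths are
computed as the span of voxel centers along a direction plus half the
voxel box support along that direction: half a voxel is the expected
offset of the continuous surface beyond the outermost included voxel
center, and unlike measuring voxel corners it does not inflate
diagonal directions (corner-based calipers overshoot round sections
by up to a full voxel diagonal).  Directions are scanned on a
2000-point Fibonacci hemisphere and refined locally; the scan runs on
convex-hull vertices, exact for convex bodies and an outer bound
otherwise.  Anisotropic voxels are scaled to μm before any distance.
On 20×10×10 μm phantoms at 1 μm voxels both axes land within 1 voxel
of truth and within 2% across in-plane rotations; degenerate masks
(single voxel, coplanar) fall back to the voxel diagonal with a
warning.

**Phantoms** are two-channel: a membrane-analog shell (normalized
ellipsoid radius 0.6–1.0 — thick enough to voxelize watertight at
1 μm) and a nucleus-analog core (radius ≤ 0.55), over dark background
with optional Gaussian noise, plus an optional in-plane rotation of
the long axis.  Real cells are neither ellipsoidal nor two-level;
the phantoms validate the measurement chain, not the biology.

## Invasion profiling

Depths are measured from the gel top (deeper positive); cells above
the top are clamped to 0 with a warning.  Bins are half-open [a, b)
of width 250 μm with the final bin closed at the 750 μm counting
maximum; deeper cells are clamped into the final bin rather than
discarded, so counts always conserve the cohort (a max depth of
1,000 μm yields the four true quartiles of a full gel).  The median
is reported with the distribution-free order-statistic 95% CI
(binomial at p = ½); the mean is reported alongside since "average
depth" can mean either.  Synthetic depths follow an exponential
truncated to the gel by rejection (not clamping), keeping the density
analytic so the sample mean and median are testable against closed
forms; the exponential is a stand-in — the real depth distribution of
invading cells is not characterized, only its density-dependent skew.

## Assay percentages

Viability and apoptosis are computed per field (typically 100
reference cells per field, 4 fields) and then averaged, so per-field
viability and death always sum to 100%.  Degradation is
100·(sample − background)/(total − background), invariant under
affine rescaling of the fluorescence readout, clipped to [0, 100]
with a warning when noise pushes it outside.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to make
Monte-Carlo bands comfortable: 200–1,000 tracks of 144 frames for
trajectory calibration, 256² fiber fields with 20 replicate seeds per
density for trend checks, 200 random ≤ 64² masks for the Lf oracle,
and 32–64³ phantom volumes.  Every stochastic test fixes its seeds;
hypothesis profiles are derandomized.

## Known limitations

- Fiber analysis is 2D per layer; no 3D fiber tracing.
- Persistent-walk and fBm generators do not model bleb-driven
  propulsion, matrix degradation or cell–fiber mechanics — only the
  statistical signatures the estimators must detect.
- Sampled skeleton fiber lengths are branch lengths, biased short in
  dense networks (trend-faithful, not absolute).
- Pore/fiber sizes from the radial spectrum depend on the dominant
  frequency of a broadband profile for random fields; they are
  comparative metrics, not absolute pore calipers.
- Axis measurements assume an approximately convex cell; deep
  concavities are bridged by the convex hull.
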