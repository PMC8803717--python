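# Methods

## The measurement this package implements

At the level of the lateral ventricle body, three structures are mutually
perpendicular: projection fibers (corticospinal tract) run inferior-superior
(z), association fibers (superior longitudinal fasciculus) run
anterior-posterior (y), and the perivascular spaces of the medullary veins run
right-left (x). Water moving along those perivascular channels elevates the
x-diffusivity in both fiber regions, while the diffusivity perpendicular to
both a fiber bundle and the perivascular direction is unaffected by it. The
ALPS index exploits this:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where Dxx/Dyy/Dzz are the diagonal elements of the diffusion tensor in the
scanner frame (no eigen-rotation), averaged over four ROIs — projection and
association area, each hemisphere. The index is computed per hemisphere
(ALPS-R, ALPS-L) and as their average (ALPS-Bil). An index of 1 means "no
perivascular elevation"; healthy adult white matter sits around 1.5.

The package provides the whole measurement chain — a synthetic phantom with
this geometry, DWI simulation, tensor fitting, ROI analysis, agreement
statistics — so the method's sensitivity to acquisition choices can be
studied without human data.

## The phantom

Geometry. The grid (default 48 x 48 x 24 voxels at 0.78125 x 0.78125 x 3 mm,
the in-plane spacing of a 200 mm FOV reconstructed at 256) is split into four
x-slabs: association | projection | projection | association, flanked by an
anterior CSF slab and air margins in z. Each region carries a diagonal
tensor: projection (0.40, 0.45, 1.40) x 1e-3 mm^2/s, association
(0.40, 1.30, 0.45) x 1e-3 — typical deep-white-matter values with the
principal axis on the correct anatomical direction. ROI centers sit at the
middle of each slab, on half-voxel coordinates, mirror-symmetric about the
midsagittal plane.

Perivascular water. A fraction f (default 0.12) of the water in both fiber
regions is perivascular: fast along x (3.0e-3 mm^2/s), restricted across it
(0.3e-3). Two signal representations are available:

* tensor mode (default): the contribution is folded into the voxel tensor as
  an additive x elevation f (D_pvs_x - Dxx); the signal is monoexponential
  and the noiseless pipeline has an exact closed form,
  ALPS = (0.712 / 0.45) = 1.582 with the defaults.
* pool mode: perivascular water is a separate diffusion pool and the voxel
  signal is (1-f) exp(-b g'D_tis g) + f exp(-b g'D_pvs g). Real tissue is not
  monoexponential, and this is what makes the fitted index depend on the
  gradient direction set: a log-linear tensor fit of a biexponential signal
  aliases the higher-order angular structure differently for 3, 12 and 30
  directions. The study harness uses pool mode so the axis-count effects have
  a mechanism; unit-level identities are stated for tensor mode.

Diffusion-time dependence. Compartment diffusivities are defined at the
reference diffusion time 35.7 ms. Two dimensionless monotone curves
s(t) = (s_inf + (1-s_inf) e^(-t/tau)) / (value at 35.7 ms) scale the tissue
tensor (s_inf = 0.90, tau = 40 ms — nearly free) and the perivascular
*contribution* (s_inf = 0.45, tau = 40 ms — strongly restricted): at longer
diffusion times less water appears perivascular, so the index falls as
diffusion time grows (29 -> 35.7 -> 40.7 ms). A per-region scalar time model
cannot do this: a factor common to a region's three axes cancels exactly in
the ALPS ratio when the two regions are symmetric. This is a simulator
convention that reproduces the observed direction of the TE effect, not a
biophysical claim. In pool mode the perivascular scale multiplies the pool
weight rather than the pool diffusivity — at b = 1000 s/mm^2 the fast pool is
essentially fully attenuated, so modulating its diffusivity would barely move
the signal.

Acquisition. Schemes pair one b = 0 volume with 3, 12 or 30 weighted
directions at b = 1000 s/mm^2. The 3-axis set is exactly (x, y, z); the 12-
and 30-direction sets are spherical-Fibonacci hemisphere lattices, frozen
with documented minimum pairwise line angles (26.3 deg and 13.8 deg) — only
the direction count matters for the questions studied here, not any vendor's
proprietary table. Echo time maps to diffusion time through the fixed pairing
65 -> 29, 85 -> 35.7, 100 -> 40.7 ms. Noise is Rician (magnitude MRI):
independent complex Gaussian noise per average at SNR 40 (b = 0, tissue) by
default, magnitudes averaged before fitting, which is what scanners do. The
two scanner profiles share the signal model and differ only in noise scale
(second scanner: 0.9 x SNR). Head position and imaging plane are both
modeled as a pitch of the anatomy about x (gradients stay plane-aligned):
defaults 8.5 deg for the infra-orbital-meatal plane tilt (midpoint of the
anatomical 7-10 deg range) and 20 deg for chin-up.

## Fitting

The tensor fit is plain OLS on log signals, solving
ln S = ln S0 - b g'Dg for the six unique elements plus ln S0 — the baseline
behavior of the standard toolchain, and simple enough that an independent
normal-equations oracle can verify it to machine precision. No weighting, no
robust reweighting, no spatial smoothing. Voxels with any nonpositive signal
are masked out, not clamped; negative fitted diagonals stay in the tensor
volume but are excluded from ROI statistics, because clamping would bias ROI
means upward. FA and MD come from the eigenvalues by the standard
definitions. The 3-axis route computes ADC_i = -ln(S_i/S0)/b per axis from
the averaged magnitudes (S0 = mean of the b = 0 volumes); on axis-aligned
noiseless tensor data it coincides with the tensor diagonal, but under the
pool signal model and noise the two routes live on different scales, so maps
and indices always carry a `source` label and are never pooled unlabeled.

## ROI conventions

Six patterns with matched centers: sphere, cube, and single-slice square at
12 or 8 px (px = in-plane pixel; a 12 px sphere is 9.375 mm across). Even
sizes have no central voxel, so centers sit on half-voxel coordinates and
membership uses voxel-center distance; z distances are scaled by the
slice/in-plane spacing ratio so shapes are physically round/cubic on
anisotropic grids. A mask clipped by the grid boundary sets a `truncated`
flag rather than failing or staying silent. Empty ROI-mask/fit-mask
intersections raise an error naming the ROI.

## Reliability statistics

ICC form: the study design is test-retest of a single measurement across
sessions, with sessions as random draws; the matching coefficient is the
two-way random-effects, absolute-agreement, single-measurement ICC(2,1),
computed from the two-way mean squares, with the McGraw-Wong F-based 95% CI.
The form is recorded in report metadata because reproduced ICCs depend on it.
Zero-variance matrices yield a flagged "degenerate" result, not an exception.
Landis-Koch bands use edges 0.20/0.40/0.60/0.80, upper-inclusive. Paired
comparisons: two-sided paired t and Pearson r (multi-session means are
averaged before testing). Condition effects across three or more levels use
a two-way repeated-measures ANOVA with subject as the random block and a
single within factor; everything is two-sided at alpha = 0.05 without
multiplicity correction.

## The simulated study

Seven subjects by default, each a jittered copy of the base phantom:
lognormal multiplicative jitter (SD 5%) applied independently per (region,
axis) and to the perivascular fraction, plus a persistent per-subject
baseline pitch (SD 3 deg) modeling fibers not perfectly aligned with the
scanner axes. A jitter common to all compartments would cancel exactly in
the ALPS ratio (the index is scale-invariant by construction), which is why
the jitter is per-axis. Sessions differ only by fresh noise realizations —
no day-to-day drift is modeled. Twelve conditions mirror the emulated
protocol grid: four matched repeats (1a-1d), plane tilt (2a) and chin-up
(2b), 4-average (3a), 30-axis/1-average (3b), 3-axis/4-average DWI (3c),
TE 100 and 65 ms (4a, 4b), and the second scanner profile (5). Everything is
reproducible from the design seed via spawned seed sequences.

`check_findings` evaluates eight study-level properties of the result table
(matched-condition ICC >= 0.8; large-ROI >= small-ROI ICC; bilateral >= min
unilateral ICC; rotation degrades ICC; 12- vs 30-axis and 12- vs 3-axis
indices differ in paired mean yet correlate at r > 0.9 / r > 0.8; the index
falls monotonically with diffusion time; a scanner noise-profile swap alone
keeps ICC >= 0.8), each reported with its numbers.

## What the phantom does and does not show

The phantom has piecewise-homogeneous regions, no partial-volume gradients,
no susceptibility distortion, eddy currents or motion, no registration step,
and its ROI centers are known exactly rather than placed on a color-FA map.
Passing tests therefore demonstrate the internal consistency and noise
behavior of the measurement chain and the *direction* of acquisition
effects, not their magnitudes in human data: simulated ICCs are optimistic
(about 0.99 at matched conditions versus about 0.83 reported in vivo)
because real between-session variance has sources the simulator omits.
The optional `assoc_shortening` parameter reproduces the known failure mode
where a short superior longitudinal fasciculus pushes an automated
association ROI off the tract; it is off by default.

## Numerical choices and problem sizes

The default 48 x 48 x 24 grid keeps a full 7-subject x 12-condition study
with all six ROI patterns under a minute of CPU while every ROI still holds
200+ voxels. Tolerances in tests mirror the regime of each identity: exact
linear-algebra paths at 1e-9..1e-12, closed-form noiseless limits at 1e-6 or
better, Monte-Carlo checks at 3 standard errors. Interpolation of acquired
matrices (128 -> 256) is not simulated; the phantom works at its native
grid, and pixel-size conversions are pure arithmetic. Whether the original
toolchain fitted OLS or WLS is not documented anywhere authoritative; OLS is
fixed here and recorded.
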