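# Methods

This note documents the models, numerical choices and limitations behind
`spirestore`.

## Forward model

A particle is a weighted point cloud (atomic coordinates with weights equal
to the atomic number Z, a uniform-density geometric shape, or a
pseudo-protein "blob").  The far-field intensity on a flat square detector
is

    I(q) = | sum_j w_j exp(i q . r_j) |^2,

with the scattering vector q = (2*pi/lambda)(s - s0) evaluated on the exact
Ewald sphere by default; a flat-Ewald (small-angle) map is available as a
flag.  The uniform sphere uses its closed-form amplitude
3(sin u - u cos u)/u^3, u = qD/2 (exact physics, and the reference the
point-cloud sampler is tested against); cube and icosahedron are filled
point clouds.  No q-dependent atomic form factors or anomalous terms are
included: the restoration task is insensitive to sub-percent scattering
physics, and the absolute photon scale is set by the intensity factor
anyway.

Two notes on symmetry and accuracy:

* Friedel symmetry I(q) = I(-q) is exact on the detector grid only under
  the flat-Ewald map; with the exact map the mirror pixel keeps the same
  beam-axis component, so detector-grid "Friedel" symmetry is broken at the
  ~1e-3 level at the default geometry.  Tests assert exact symmetry under
  the flat map and bound the curvature-induced deviation.
* The bulk simulation engine (`engine="fft"`) exploits the flat-Ewald
  identity that the detector samples the transform of the beam-axis
  projection of the density: points are deposited on a padded 2D grid
  (cloud-in-cell, deconvolved by the kernel's sinc^2), transformed with one
  FFT, and cropped.  It agrees with the direct sum to ~2e-4 relative at
  pad factor 2 and is ~1000x faster; the exact direct sum remains the
  default for `simulate_pattern`.

## Study geometry and the synthetic ensemble

The reference conditions are 8 keV photons, a 15 cm detector distance and
128x128 output patterns.  The native (pre-binning) detector side of the
published setup is not stated; we fix the effective binned pixel to 800 um
by simulating on a 256-pixel grid of 400 um pixels and sum-binning 2x2
(which also reproduces the averaging of neighbouring local maxima that
downsampling causes).  This choice is calibrated to the reported speckle
statistics: with it, pseudo-proteins spanning 10-100 kDa produce central
speckles of ~12-34 pixels with an ensemble mean of ~18 pixels, and 75% of
patterns below 25 pixels.

Pseudo-protein blobs stand in for randomly drawn Protein Data Bank
structures so that nothing needs to be downloaded: the point count scales
linearly with molecular weight (~85 heavy-atom-scale points per kDa) and
the radius follows the globular mass-radius law R = 0.66 nm * (M/kDa)^(1/3)
with a mild volume-preserving random axis stretch for anisotropy.  Blobs
reproduce the speckle-size spread of a protein ensemble but not secondary
structure, internal density fluctuations, or the heavy-tailed shape
diversity of the PDB; conclusions about *absolute* restoration error on
real protein ensembles cannot be drawn from them, while noise laws,
filter/network orderings, and mask-width trends transfer.

Corruption follows the published protocol: per-pattern max-normalization,
multiplication by the intensity factor f, and per-pixel Poisson sampling
(K_i ~ Poisson(f * I_i)).  Each pattern has an independent random stream
derived from (dataset seed, pattern index), so datasets are reproducible
and order-independent.  The linearized noise floor obeys
E[(K/f - I)^2] = mean(I)/f exactly.

## Log-scale normalization

Intensities span several decades, so restorer inputs and targets are
compressed with

    I_hat = log(1 + c*I) / log(1 + c*I_max),

which maps [0, I_max] monotonically onto [0, 1] and inverts exactly.  The
published formula is only rendered as a figure in our source text, so the
constant c is configurable; dataset builders use c = f on linearized counts
K/f (equivalent to log1p on raw counts) and c = 1000 for the noiseless
inpainting study.  The reference maximum is global (the unit maximum of the
normalized clean patterns), not per pattern, so relative intensities across
a dataset are preserved.

## Binary filter

The inverse transform of the intensities is the particle's spatial
autocorrelation, compactly supported in twice the particle extent when
oversampled.  The benchmark denoiser zeroes the autocorrelation outside the
support derived from the noiseless pattern (threshold 1e-4 of the peak
magnitude, centro-symmetrized) and transforms back, clipping negative
intensities.  Masked pixels are zero-filled first, deliberately: the
method's known fragility to missing data must be reproducible, not
repaired.

One numerical subtlety: a truncated sampled pattern is not exactly
band-limited, so a small fraction of autocorrelation mass leaks outside the
support and the self-support "identity" holds only to about 3x the
threshold.  The exact identity (< 1e-9) is verified on grid-commensurate
particles whose points sit on the detector-conjugate lattice, for which the
discrete autocorrelation is exactly compact.

## U-Net restorer

No deep-learning framework is part of the dependency set; the network is
implemented directly in NumPy (im2col convolutions with explicit backward
passes, verified against central finite differences).  Architecture:
symmetric encoder-decoder, two 3x3 conv + ReLU per level, 2x2 max-pool,
nearest-neighbour upsampling, skip concatenations, 1x1 sigmoid head;
feature-unit dropout (rate 0.5) after the last two downsampling steps
during training.  Loss is pixel-mean binary cross-entropy against the
noiseless normalized target (including masked pixels -- inpainting needs
gradients there), optimized with Adam.  The full-protocol configuration
(128 px, depth 4, 32 base channels, 20 epochs, batch 32 -> 294 steps/epoch
at 9900 images with 5% validation) is expressible but not exercised by the
test suite; the desk preset is 64 px, depth 3, 16 base channels, 8 epochs,
batch 8, learning rate 2e-3, which trains in ~2 minutes per condition on
one CPU core.  One model is trained per (noise, mask) condition.

Desk-scale restoration quality is far from the published full-scale
numbers (hundreds of times less data and compute); the suite therefore
checks orderings and win-rates, not absolute MSE: the trained denoiser
must beat the noisy input on >=90% of held-out patterns, and inpainting
error must grow with mask width.

For the mask-width comparison the error is evaluated on a *fixed* pixel
set -- the central 2-row band, which is masked in both conditions.
Averaging each condition over its own mask instead confounds the
comparison: a wide stripe dilutes the bright central pixels with many
weak ones and can appear spuriously "better" per pixel.  The fixed-set
comparison measures exactly the reported effect that rows deeper inside a
mask are recovered worse.

## EMC orientation recovery

Expand-maximize-compress with a fixed quasi-uniform rotation grid
(super-Fibonacci sampling on S^3; identity prepended; equal weights).
Expand: trilinear slices of the 3D model on each rotated flat-Ewald
detector surface (`qv @ R`, matching the particle-rotation convention of
the simulator).  Maximize: posterior responsibilities per pattern under a
Poisson likelihood on photon counts or a Gaussian likelihood for
continuous restored intensities.  Compress: responsibility-weighted
tomographic re-insertion (weighted mean per voxel).  The model grid can be
supersampled (voxel = detector q-spacing / s); at s=1 the trilinear
interpolation error (~14% relative) exceeds the inter-orientation
intensity contrast of small test patterns, while s=3 makes slices accurate
to a few percent.

The Gaussian likelihood uses a per-pixel variance scale s_i = W_i + eps by
default ("intensity" weighting): photon noise grows with intensity, and a
uniform sigma lets the bright central speckle drown the orientation
information carried by the outer speckles (with uniform weighting the
rotation of even a perfectly known model cannot be identified on desk-scale
patterns).  A scalar sigma estimated from the median per-pixel residual
scale multiplies it, annealed geometrically from 6x down to 1x
(deterministic annealing) to delay hard assignment while the model forms.
The model is initialized from the orientation-averaged insertion of all
patterns.  With "nearest" interpolation the M step is the exact maximizer
of the EM objective and the data log-likelihood is provably non-decreasing;
with trilinear kernels it is monotone to numerical tolerance.

Blurred EMC convolves the accumulated intensity mass and insertion weights
with a 3D Gaussian (standard deviation below the Shannon-pixel equivalent,
lambda*L/(2*D*p) detector pixels) after each compression, spreading each
measurement over neighbouring voxels; at 20 patterns it leaves measurably
fewer empty voxels than the plain variant.

Rotation error is the mean angular distance after an exhaustive search
over gauge rotations (the relative rotations truth x estimate^-1 serve as
candidates), with a per-pattern minimum over the Friedel ambiguity (a
half-turn about the beam axis gives the same flat-Ewald slice of a
Friedel-symmetric model).

**Known limitation -- ab initio convergence.**  From uninformed starts at
desk scale (16-32 px detectors, tens to hundreds of patterns), the EM
iteration reliably settles in self-consistent local optima in which
patterns are assigned mutually inconsistent orientations; annealing
schedules, blur schedules, multi-resolution grids and stochastic-EM
variants do not escape them.  This mirrors the data-hunger of the
published full-scale benchmark, where plain EMC needs roughly 700 noisy
patterns to converge.  The implementation itself is validated three ways:
slicing a directly evaluated 3D intensity reproduces the simulated pattern
to interpolation accuracy; the true assignment is a stable fixed point of
the iteration with the best observed likelihood; and patterns held out of
a model assembled from disjoint patterns orient to well below the
rotation-grid spacing (~80% exact grid matches).  The acceptance report
therefore carries both the ab initio rotation error and the held-out
orientation error.

## Metrics

MSE is computed on the linear intensity scale with the clean reference
max-normalized to 1, over the full frame unless a pixel subset is
requested; it is preserved by unitary Fourier transforms, so it equals the
autocorrelation-space error.  PSNR = -10*log10(MSE) for the unit peak,
which reproduces the published MSE/PSNR table pairs to printed precision
(one virus-like-particle row is internally inconsistent beyond rounding
and is excluded from the fixture).  Speckle size is the distance between
the first strict local minima above and below the central maximum along
the central column (optional 3-point smoothing for noisy diagnostics,
off by default).  The best-case real-space check inverts
sqrt(I) * exp(i*phi_true) with the simulation's own phases.

## Problem sizes

The test suite and the acceptance script run entirely on one CPU core:
datasets of 60-300 patterns at 64x64, U-Net presets as above, EMC on 16 px
detectors with 121-271 rotations and 32^3-48^3 voxel grids.  Full-protocol
sizes (10 900 patterns, 128 px, 20 epochs, GPU-scale EMC) are supported by
the same code paths through configuration.
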