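# Methods

This note documents the models, conventions and numerical choices behind
`fastpaint`, in the order the pipeline uses them.

## Coordinate and rendering conventions

Localization coordinates are 0-based camera-pixel floats with pixel centers
at half-integer positions (`x = 0.5` is the center of the first pixel), the
convention used by Picasso-style localization files, which this package
reads and writes unchanged (HDF5 record array named `locs` with fields
`frame`, `x`, `y`, `photons`, optional `lpx`/`lpy`; YAML sidecar with
`Width`, `Height`, `Frames`).

Rendering is a pure 2D histogram on a grid oversampled 16× relative to
camera pixels: a localization at `(x, y)` increments exactly one bin,
`(⌊16·y⌋, ⌊16·x⌋)`, with half-open bins, so a point exactly on the
right/bottom field edge is out of the field and dropped.  Before clipping
to the 16-bit range the pixel sum equals the number of in-field
localizations; this count-conservation property is what the test suite's
brute-force oracle checks.  Gaussian-weighted rendering is deliberately not
the default — the histogram is the simplest faithful reduction of the
localization set and the one whose properties (additivity, permutation
invariance) are exactly testable.

Widefield images live on the camera grid and are upscaled by nearest-
neighbour block replication (each camera pixel becomes a 16×16 block,
values untouched), keeping the upscaling pixel-exact and testable; bilinear
interpolation is available behind a flag.

The fast-protocol frame subset is a temporal *prefix* — the first `n`
frames of an `N`-frame movie — because a shortened acquisition is a prefix
in time, not a random sample of frames.

## Microtubule simulator

One simulated field of view is 16×16 camera pixels rendered at 256×256
super-resolution pixels (configurable).  Per image:

- **Filament count** ~ Poisson(`structure_dense`, default 8), clamped to at
  least 1.
- **Geometry**: each filament is a discrete worm-like chain — fixed arc
  step 0.25 camera px, Gaussian turning angle per step with sd
  `curvature_sigma` (default 0.12 rad, giving gently curved microtubule-like
  arcs; near 0 the chains become straight rods) — reflected at the field
  walls, smoothed with a cubic parametric spline, and clipped to the field.
  Contour lengths are uniform in 0.5–1.5 field side lengths.
- **Localizations**: counts ~ Poisson(density × contour length) with
  default linear density 60 localizations per camera pixel of filament
  (enough to make ground-truth lines quasi-continuous at 16× oversampling);
  positions uniform along arc length plus isotropic Gaussian error of sd
  1/16 camera pixel (one super-resolution pixel, a typical DNA-PAINT
  localization precision relative to the render grid); jittered points
  leaving the field are discarded.  Frame indices are uniform over a
  nominal 30,000-frame movie, so frame-budget experiments work on simulated
  tables; photon counts are exponential (mean 5,000) and carried for format
  fidelity only.
- **Sparse channel**: binomial thinning — each localization kept
  independently with probability `sparsity` (default 0.1, the fast
  protocol's ~10% raw-data fraction).  Thinning the table rather than the
  image makes the sparse channel exactly the render of a sub-experiment.
- **Widefield channel**: the *full* emitter set (real widefield images see
  every fluorophore, not a temporal subset) binned at camera resolution,
  blurred with a Gaussian PSF of sd 1.3 camera pixels (diffraction-limited
  scale for a high-NA objective at visible wavelengths with binned pixels),
  peak-normalized, and block-upscaled onto the super-resolution grid.

**Intensity scale.**  Raw histogram counts are small integers (1–5 on a
filament), which would leave 16-bit training images essentially black: MSE
training gradients and the [0, 255]-scale metrics would both operate in the
last few codes of the dynamic range, and near-empty pairs would saturate
PSNR/SSIM.  Triplet images therefore apply a fixed linear gain
(`intensity_scale`, default 4,000 counts⁻¹, clipped at 65,535) so typical
filament pixels land mid-range, emulating the display scaling that real
rendered 16-bit training images carry.  The gain is linear, so the
sparse-to-ground-truth intensity ratio still estimates the sparsity (tested
to 3 Monte-Carlo sigmas); `render_histogram` itself remains unscaled counts.

Determinism: a dataset is a pure function of (config, seed).  Each image
draws its own child seed from the master seed, recorded in the manifest, so
any single triplet can be regenerated in isolation.

**What the simulator does not emulate** — camera noise (EMCCD/sCMOS read
noise, gain), DNA hybridization kinetics and frame-by-frame blinking,
out-of-focus background, drift, 3D structure, and non-microtubule
morphologies.  Passing tests therefore show the pipeline's operations and
the network's ability to restore thinned filament renders under the stated
model; they are not evidence about performance on real acquisitions.

## Tiling and splitting

Training pairs are cut on a non-overlapping grid anchored at (0, 0) with
partial edge tiles dropped (padding would inject artificial dark borders).
The standard tile sizes are 256 and 512 px; smaller powers of two are
accepted for reduced-scale runs.  Near-empty tiles are removed by an
automated content filter (ground-truth nonzero fraction < 0.002 by
default) — a reproducible surrogate for manual visual curation.  The split
labels round(5%) of tiles as test, drawn uniformly without replacement from
a seeded generator, and rejects datasets whose training side falls below
200 pairs.  Splitting by source image (to avoid leakage between neighboring
tiles of one field) is supported; the default is by tile.

## Restoration network

Classic U-Net: `depth` encoder stages of (3×3 conv, ReLU) ×2 followed by
2×2 max-pool; a bottleneck double-conv; decoder stages of 2× nearest
upsample, channel-halving 3×3 conv, skip concatenation and double-conv; a
1×1 output head.  Defaults: depth 4, base width 64, input channels 1
(sparse) or 2 (sparse + widefield, fused by input concatenation).

Because no autodiff framework is part of the package's dependency set, the
network is implemented directly on NumPy arrays: convolutions are lowered
to GEMM via `sliding_window_view` (im2col), each layer carries an explicit
backward pass, and the optimizer is Adam (lr 1e-4, β = 0.9/0.999,
batch 4 by default).  The backward pass is verified against central finite
differences in double precision (relative error ~1e-9); production runs
use single precision for throughput.  All initialization and shuffling
randomness flows from explicit seeds, so training is bit-reproducible on a
fixed platform.

Inputs and targets are normalized to [0, 1] by dividing by 65,535; the
loss is plain MSE, matching the RMSE evaluation metric; predictions are
rescaled, rounded and clipped back to 16-bit on output.  Checkpoints are
self-describing `.npz` files (architecture config + weights + provenance),
and save → load → predict is bit-identical.

Panorama stitching places tiles at their origins; non-overlapping
placements are bit-exact copies and overlaps are averaged, then rounded to
16-bit.

## Evaluation metrics

RMSE, PSNR and SSIM are computed on a [0, 255] scale; 16-bit images are
divided by 257 first, keeping the 255 constants meaningful.  PSNR is
piecewise: exactly 100 when RMSE = 0, else `20·log10(255/RMSE)`.  SSIM uses
*global* image statistics (population mean/sd/covariance over the whole
image) rather than the common 11×11 sliding window — the windowed variant
exists behind a flag — with the canonical numerator term `2·cov + c2`;
population normalization makes `ssim(a, a) = 1` exact for every image,
constant ones included.  Stabilizers default to c1 = (0.01·255)²,
c2 = (0.03·255)².

## Problem sizes used in the automated checks

The test suite exercises the full-size defaults for contracts and
statistics, and a reduced-scale study for learning: 220 triplets at 64×64
(6 filaments average, sparsity 0.1), a depth-3 / width-16 network trained
20 epochs at learning rate 1e-3, evaluated on the 5% held-out tiles, where
restoration must beat the sparse input in mean PSNR and mean SSIM and on at
least 80% of tiles.  These sizes were chosen so the whole suite runs on a
single CPU core in a few minutes; the improvement margins are large (≈ +2 dB
PSNR, ≈ +0.3 SSIM at 20 epochs), so the check is far from its threshold.

## Known limitations

- Global-statistics SSIM saturates for nearly-empty image pairs; the
  simulator's intensity gain mitigates this but very sparse fields still
  compress the metric's range.
- The NumPy network is CPU-bound and single-threaded through BLAS; it is
  sized for 64–256 px tiles and hundreds of epochs, not for large-scale
  training.
- Bit-level training determinism holds for a fixed platform/BLAS build;
  across different BLAS implementations only statistical reproducibility
  is guaranteed.
- The simulator's localization density, PSF width and filament geometry
  are plausible defaults, not fitted to any particular instrument.
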