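# Methods

## Model

A cine sequence is modelled as `N` single-channel frames of one periodic
motion cycle, intensity-normalized to [0, 1] jointly over the sequence.
Registration estimates pull/backward displacement fields `u_n` on the
template grid, `registered_n(x) = frame_n(x + u_n(x))`, with bilinear
interpolation and clamp-to-edge boundary handling (replicating border
intensities avoids the spurious dark borders that zero filling would feed
into SSD values and template averages).

The training loss is

`L = Similarity + sum_p lambda_p R_p + lambda_c * Constraint`

* **Similarity** — groupwise SSD: the per-pixel temporal variance of the
  registered frames around their temporal mean, summed over the region of
  interest. Alternative: negative windowed squared normalized
  cross-correlation (NCC) of each registered frame against the template,
  accumulated over frames. NCC windows are square (default 9 px); local
  statistics use zero-padded box sums with a constant window count, which
  keeps the operator exactly self-adjoint for the analytic gradient, and
  the score aggregates only windows with full support so that identical or
  affinely related images score exactly 1 everywhere counted.
* **Regularization** — `R1`/`R2`: squared first/second spatial derivatives
  of the displacement (the second-order term carries the doubled mixed
  derivative). `R3`/`R4`: squared first/second *circular* (mod-N) temporal
  differences, coupling the last frame to the first. Spatial derivatives
  act on `u`, not on `T = x + u`, so the identity transform costs zero
  (`regularize_displacement=True`; the `T` variant is available).
* **Constraint** — squared temporal-mean displacement per pixel and
  component: over one closed cycle the displacements of a material point
  should sum to zero.

All terms carry exact analytic gradients with respect to the fields
(through the warp for the similarity), verified against central finite
differences to < 1e-4 relative error.

## Numerical choices

* Spatial first differences: forward, replicate boundary (last difference
  zero). Second differences: central, zero on the boundary slices — this
  makes `R2` vanish exactly on affine fields. Temporal differences:
  circular.
* Warp derivatives: where the sampled coordinate saturates at the image
  edge, the field derivative is zero (clip subgradient).
* Degenerate normalization (min = max): all-zero output rather than NaN.
* SSD with < 2 frames, empty region masks, shape mismatches: validation
  errors.
* NCC windows with (numerically, < 1e-10) zero variance contribute 0.

## Default loss configuration

`lambda3 = 1e-7` (first-order temporal smoothness) is the reference
configuration for clinical-scale cine registration, selected by greedy
forward selection. The package default additionally activates the
periodicity constraint at `lambda_c = 1e-2`. The reason is a failure mode
of the unconstrained groupwise SSD that becomes reachable at small image
sizes: a network can drive the SSD down by mapping moving content onto
nearby *static* regions with large, nearly time-constant displacements
(any static target region works, whatever its texture, because each frame
then samples the same values). Direct per-sequence optimization of the
fields does not fall into this mode, but shared-weight training with a
normalized optimizer does: the degenerate direction is consistent across
sequences while the honest direction varies, and on a 64x64 grid the
static regions are only ~10 px away. The cycle-closure constraint
penalizes exactly this mode — time-constant drift has a nonzero
temporal-mean displacement — and restores honest recovery (endpoint error
< 1 px versus > 10 px drift) while costing nothing on truly periodic
motion. NCC similarity resists the mode as well (constant targets have
zero local variance and score 0). Set `lambda_c = 0` for the
lambda3-only configuration.

## Network

A reduced U-net: encoder/decoder with skip concatenation, 3x3
convolutions, LeakyReLU(0.2), 2x max-pool / nearest upsampling, and a 1x1
output convolution initialized near zero so the untrained network starts
at (almost) the identity transform. Default depth 3 with filters
(8, 16, 16), ~19k parameters: cine motion is smooth and low-frequency, so
a small network trains in minutes on one CPU and regularizes implicitly;
larger variants, e.g. depth 4 with (16, 32, 32, 32), are available via
`NetConfig(filters_per_level=...)`. No normalization layers: the batch is
one sequence and batch statistics would couple frames. Tensors are
channels-last (B, H, W, C), matching the field layout (N, H, W, 2). The
implementation (forward, backward, Adam) is self-contained NumPy and
gradient-checked in the tests.

Training: per epoch, sequences are visited in a seeded random order; per
sequence, `L + 1` iterations each take one Adam step (lr 1e-4, batch = all
N frames) and then replace the template by the average of the registered
frames computed before the step; the template is a constant to the
optimizer — no gradient flows through its history. Prediction runs the
same loop without updates. Any non-finite loss aborts with the offending
sequence and iteration. Defaults `L = 5`, 10 epochs.

## Template selection

At iteration 0 the template is the geodesic medoid of the frames:
residual-complexity dissimilarity `RC(a,b) = sum log(1 + c_i^2/alpha)`
over the orthonormal 2D DCT-II coefficients `c` of `a - b`
(`alpha = 0.05`; plain SSD available), kNN graph with `k = 4` neighbors
(ties to the lower index; `k` auto-increments until the graph is
connected), Dijkstra shortest paths from every node, and the frame with
the minimal distance sum (ties to the lowest index). `alpha` and `k` are
package choices; selection is insensitive to them on phantoms because
cine frames form a single well-connected manifold.

## Synthetic phantom

The generator emulates the statistical structure of short-axis cine MR
slices: a textured quasi-circular object (concentric rings with a soft
edge, or random blobs, plus a weak smooth background texture so no region
is exactly flat), smooth periodic elastic motion, joint [0, 1]
normalization, and additive Gaussian noise (added before normalization).
Motion: `u_n(x) = A sin(2 pi n / N) s(x)` with `s` a band of radially
inward Gaussian bumps (systolic-contraction-like) or random-direction
bumps, `max |s| = 1`. Frames are produced by pull-warping the base image
with `u_n`; the returned ground truth is `u_n` itself, so a perfect
registrar recovers approximately `-u_n` (the first-order inverse), with
an `O(|u||grad u|)` inversion bias well below the evaluation thresholds
at the default amplitude. Defaults — 64x64, N = 10, amplitude 3 px, noise
0.01 — are the desk-scale study conditions used by the tests and the
acceptance script.

What the phantom does *not* model: MR acquisition physics (coil
sensitivities, k-space noise, motion artifacts), through-plane motion,
anatomical variability, pathology, or non-periodic motion. Passing the
phantom study demonstrates that the estimator recovers smooth periodic
motion it can represent, not clinical performance.

## Evaluation

SSIM (Gaussian window sigma 1.5, 11x11, K1 = 0.01, K2 = 0.03, dynamic
range 1) between selected registered frames and the final template; the
sample takes two *distant* frames per sequence (peak contraction and
rest — systole/diastole analogues) to limit within-sequence correlation.
SER (dB, capped at 300 for identical images), histogram mutual
information (64 bins over [0, 1], in bits; note the plug-in estimator's
upward bias of about `(bins-1)^2 / (2 N ln 2)` for independent inputs),
and global Pearson correlation (0 with a warning for constant images) are
standard auxiliary metrics. Paired one-sided t-tests with exact binomial
sign tests alongside; identical samples return p = 0.5 / 1.0 with a
warning.

Forward selection searches the five loss weights greedily (two candidate
values each: 1e-7/5e-7 for the derivative weights, 1e-7/1e-5 for the
constraint): stage 0 trains the all-zero configuration; each stage trains
every remaining weight at every value on top of the current selection
(stage 1: 10 networks, stage 2: 8), keeps the best value per weight by
median paired SSIM difference, activates the best weight if its t-test is
significant at 0.05, and stops otherwise. Failed cells are skipped with a
warning.

## Reconstruction demo

Single-coil row-undersampled acquisition: unitary frame-wise 2D FFT,
ceil(rows/AF) lines kept per frame (a fixed central band of 8% of rows
plus seeded uniform-random lines; the all-uniform pattern is available).
Reconstruction solves the l1-regularized problem with the motion operator
fixed after one estimation on the zero-filled images: soft-thresholding
on the circular temporal differences of the motion-compensated sequence,
a few gradient steps on the splitting term with the warp adjoint
approximated by negated-field warping, and a hard data-consistency
projection (replace sampled lines by the data) every sweep. By
construction AF = 1 returns the fully sampled reconstruction exactly and
`lambda = 0` returns the zero-filled one. Defaults: `lambda = 0.005` (for
unit-normalized intensities), 30 sweeps, step 0.2. The scheme is a
deliberately simple proximal splitting, not a replication of any specific
published solver, and uses one outer motion iteration only.

## Known limitations

* The iteration map (register, re-average the template) is only
  approximately a fixed point after the default desk-scale training
  budget (1800 steps); per-iteration SSD can rebound by ~1-2% after the
  initial drop. Training the same pipeline ~3x longer makes the trace
  monotone and roughly halves the SSD again.
* Prediction is exactly permutation-equivariant (frame-wise network,
  permutation-invariant template construction), so frame ordering can
  only influence results through the temporal terms of the training loss.
* The warp adjoint in the reconstruction is the negated-field
  approximation, exact only for small, smooth fields.
* Single 2D slices only; no multi-slice or 3D coupling; multi-coil data
  is not supported by the solver (sensitivity maps are accepted by the
  problem container but rejected at solve time).
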