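# Methods

## Problem and scope

Absolute (reference-free) electrical impedance tomography reconstructs the
conductivity distribution inside a body from a *single* frame of boundary
voltage measurements, without subtracting a baseline frame. The package
implements the full desk-scale pipeline for a 16-electrode circular domain
in adjacent-drive / adjacent-measurement mode: synthetic phantom generation,
FEM forward simulation with the complete electrode model, the electrical
impedance map (EIM) representation and its rotation symmetry, a
rotation-aware neural reconstruction network trained on the synthetic data,
a Gauss-Newton baseline, and GREIT-style figures of merit adapted to
absolute images.

## Forward model

The conductivity equation is discretised with P1 triangles on a structured
disc mesh built from concentric rings (`16 * n_rings**2` elements; default
`n_rings = 14`, 3136 elements). The mesh is **exactly 16-fold rotationally
symmetric**: each angular sector is triangulated combinatorially (rational
arithmetic) and replicated by index shifts, so rotating a per-element field
by one electrode pitch is an exact permutation. This is what lets the
rotation <-> diagonal-shift consistency of the EIM be verified at the 1e-3
relative tolerance (measured: ~1e-12 on the symmetric mesh).

Electrodes follow the complete electrode model: finite-width boundary
electrodes (default arc 2*pi/32, quantised to an even number of boundary
segments centred on the electrode node) with per-electrode contact
impedance (default 1e-2 model units — a stand-in; the reference simulator's
default constant is not published). Unit current is injected through each
of the 16 adjacent pairs; the 13 valid four-probe adjacent voltages per
injection give the 208-value frame. The system (sparse, with a zero-mean
Lagrange constraint on electrode potentials) is factorised once per
conductivity and solved for all 16 injections.

Verified properties: reciprocity (~1e-16 relative), the conductivity/contact
scaling law (~1e-12), and agreement of the adjoint Jacobian with finite
differences (~2e-4, FD-limited).

The domain is 2-D: phantoms are the z = 0 slices of 3-D shape masks, the
forward solve and rasters are planar. A 3-D cylindrical solver could be
substituted behind the same interface; slice imaging is the use case.

## Synthetic phantoms (the stated world)

* Background conductivity: log-uniform on [1e-5, 1] S/m.
* 1-4 enclosures per phantom (uniform; the count is a free choice — the
  source material shows multi-target phantoms but states no number).
* Shapes: unit sphere / cube / octahedron masks (closed inequalities),
  pushed through `v' = (R(v - t)) / s` with per-axis scale uniform on
  [0.1 r, 0.8 r], three intrinsic Euler angles uniform on [0, 2*pi), and
  translation components uniform on [-0.8 r, 0.8 r] with the in-plane norm
  resampled to stay within 0.8 r ("well inside the boundary" is not
  quantified in the source; 0.8 is this package's choice).
* Enclosure contrast: log-uniform on [1e-2, 1e2], multiplying the
  background. Overlapping enclosures: last writer wins.
* Per-region multiplicative perturbation: each painted region gets its own
  std, log-uniform on [1e-8, 1e-2] (the distribution over that range is
  unstated; log-uniform matches the other range samplings).
* Contact impedance: per-electrode multiplier N(1, std) with
  std in {1e-5, 1e-3, 1e-1}.

Ground-truth rasters (64x64, pixel-centre sampling, x right / y down,
domain centre at pixel (31.5, 31.5)) evaluate the *stated* analytic masks,
not the perturbed element field: the perturbation models measurement-side
tissue inhomogeneity, while the learning target is the clean two-level
image. Pixels outside the inscribed disc take the background value.

Enclosures whose z-extent misses the z = 0 slice are legal (warning only):
they perturb the voltages like real out-of-plane structures while leaving
the slice image unchanged.

## EIM and augmentation

The 16x16 map holds injection rows x measurement columns with 48 structural
zeros on the circular sub/main/super-diagonal band (16*13 = 208 data cells).
Rotating the conductivity counterclockwise by n pitches shifts the map
cyclically by +n along *both* axes — the diagonal shift, which the package
uses everywhere (a column-only shift is inconsistent with the forward
physics; verified against the solver at 1e-12).

Augmentations:

* thermal/jitter: per-cell multiplier N(1, std), default std 1e-6;
* quantisation: per-cell additive N(0, std), default std 1e-8;
* channel gain: one multiplier per injection row. The source formula
  prints a zero-mean draw, which would erase whole rows; the default here
  is N(1, std) (gain *spread*), with the literal zero-mean form behind
  `mean_zero=True`.
* rotation expansion: each sample plus 15 copies (shifted map, rotated
  raster);
* alpha-blending: targets combine linearly, voltages harmonically
  (`(a/U1 + (1-a)/U2)^-1`, constant-current Ohm's law). Adjacent voltages
  can take opposite signs, so the harmonic denominator can vanish; cells
  within 1e-12 (relative to the larger reciprocal) of zero fall back to the
  linear blend. Blending alpha is uniform on [0, 1] per pair, drawn at
  training time by pairing each batch item with an item of an independently
  shuffled batch.

Order at dataset build time: rotation expansion, then measurement noise;
blending happens inside the training loop.

Image rotation by k * 22.5 degrees is a sparse linear operator composed as
`(exact 90-degree permutation)^(k // 4) @ (bilinear rotation by
(k % 4) * 22.5 degrees)`, so quarter-turn multiples are exact pixel
permutations and `R[k + 4n] = P90^n R[k]` holds exactly. Target rotation
restores out-of-disc pixels verbatim (the background is constant there, and
bilinear corner artefacts would otherwise leak in).

## Network

Input 16x16 map -> five 5x5 stride-1 convolutions with **circular padding**
on both axes (the map is periodic; receptive field 1 + 5*4 = 21), each
followed by layer normalisation (over all features of a sample, per-channel
affine) and a leaky rectifier (slope 0.01). Channels (32, 64, 128, 128, 128)
by default, so the final feature block is 128 x 16 x 16 and each injection
row carries 16 columns x 128 channels = a 2048-vector: the 16 x 2048 head
input. No pooling anywhere.

Row k's 16 column blocks are cyclically un-rotated by k before the head
("canonicalisation"), making the 16 row vectors *permute* cleanly when the
input map shifts diagonally. A single dense head (2048 -> 2048, leaky
rectifier, dropout 0.1, -> 4096) is shared across the rows — 16 passes of
one 2048-vector. Each row's 4096 output is a canonical 64x64 image,
rotated back by k * 22.5 degrees and averaged; a softplus keeps the output
conductivity positive (needed by the MSLE domain).

Equivariance: the conv stack is exactly equivariant to diagonal shifts
(circular padding); with canonicalisation and rotate-and-average
aggregation, shifting the input by n in {4, 8, 12} rotates the output by
exactly n * 22.5 degrees (pixel permutation; measured equal to within
float-summation reordering, < 1e-12). For other n the equivariance is
approximate (bilinear rotations do not compose exactly); it is documented,
not asserted.

Everything — forward pass, backprop, Adam — is NumPy. The circular
convolutions are evaluated in the Fourier domain (circular padding makes
them exactly diagonal there; verified against direct evaluation to 1e-14),
and the dense head is BLAS-batched over samples x rows. Gradients of every
layer are finite-difference checked in the test suite.

## Losses and training

Composite loss as printed: `Ltotal = Lw2 + 0.1 * TV + 1e-6 * MSLE`, with

* `Lw2`: sum of squared weights (biases and normalisation gains excluded).
  The source prints a plain (unsquared) sum, which is sign-indefinite and
  not a penalty; the literal form is available behind `squared=False`.
* `TV`: anisotropic total variation, in-grid forward differences, no
  wraparound.
* `MSLE`: mean squared log1p error over all 4096 pixels — insensitive to
  the order of magnitude of the conductivity, which spans five decades.

As printed, the composite puts weight 1 on the weight penalty and 1e-6 on
the data term; training under it collapses toward zero weights. The package
therefore ships two presets: `as_printed` (1, 0.1, 1e-6) and `sane`
(1e-6, 0.1, 1) — the suspected-typo correction — and the training smoke
tests use `sane`. Inside the training objective the per-image TV sum is
normalised by the number of pixel pairs so that the 0.1 weight is
commensurate with the per-pixel MSLE term; the standalone `loss_tv`
operation keeps the raw printed sum.

Training: Adam (lr 1e-3), batches of 32, alpha-blended batch pairs,
dropout 0.1, plateau learning-rate decay (patience 10 epochs without
validation improvement, then lr x 0.3 — a 70 % reduction). Leaky-rectifier
slope, patience and initial lr are unstated in the source and are package
defaults. Fully seed-deterministic.

## Gauss-Newton baseline

Minimises `1/2 ||F(exp(m)) - V||^2 + 1/2 lambda ||L (m - m0)||^2` over
log-conductivity from the best-fit homogeneous start `m0` (scalar fit via
the 1/sigma frame scaling). Regularising about the start makes the
lambda -> infinity limit return the homogeneous image, the expected
Tikhonov behaviour for absolute EIT; the prior matrix and iteration count
are unstated in the source, so identity prior and max 10 iterations are
the defaults (an element-adjacency Laplacian prior is available). Steps
solve the normal equations in data space (Woodbury, 208x208) with a
halving line search; the hyperparameter is chosen by sweeping lambda and
picking the best position error, since an L-curve criterion is reported
not to work for reference-free EIT.

Reconstruction-quality tests simulate on a finer mesh than they invert on
(inverse-crime guard). The homogeneous-constancy test deliberately uses a
single mesh: the property under test is that homogeneous data admit a
constant minimizer, and a mesh mismatch would inject discretisation error
that small-lambda GN fits as spurious structure.

## Figures of merit

For absolute images the scalar **median** is subtracted first (robust
background removal; an ideal two-level image then has background exactly
zero). The evaluation mask takes pixels strictly beyond half the extreme
value (minimum for low-conductivity targets, maximum for high). AR is the
in-mask sum; PE the Euclidean distance of the unweighted mask centroid to
the true target centre, in pixels of the 64x64 grid (an
amplitude-weighted centroid is available behind a flag); RNG the
population std of out-of-mask pixels. Series summaries report mean and
*sample* std per metric, excluding (and counting) undefined entries. The
true position is the enclosure's analytic centre projected to the z = 0
plane, converted to pixel coordinates.

PE is reported in pixels; comparisons against numbers produced under other
conventions need this stated.

## Desk-scale choices and what green tests establish

The published experiments behind the headline comparison tables used an
unpublished trained model, a physical saline tank and unstated GN
hyperparameters, so they are not reproducible here. What the suite
establishes instead:

* all structural constants (208/48 cells, receptive field 21, 16x2048
  head, 64x64 output) hold by construction and are recomputed, not
  asserted;
* the physics the architecture exploits (rotation <-> diagonal shift) holds
  on the simulator to 1e-12;
* training end-to-end *works*: 50 epochs on 512 samples (32 phantoms x 16
  rotations, standard sampling distributions with one enclosure per
  phantom, on a 1600-element mesh) with a width-reduced configuration
  (channels 8, 16, 16, 16, 16; receptive field still 21; head 16 x 256)
  cuts validation MSLE by ~500x and localises an unseen off-centre target
  to ~5 px. This demonstrates the pipeline, not the published model's
  accuracy: the full-width network, larger datasets and longer schedules
  are a matter of budget, not code.

Smoke-training evaluation world: a single low-conductivity sphere
(contrast 0.1, radius 0.2 r) on a 0.2 S/m background — mid-range values
chosen once as a representative tank-like scenario.

## Known limitations

* 2-D domain; 16 electrodes and adjacent-adjacent mode are fixed.
* Bilinear rotations make non-quarter-turn equivariance approximate.
* The nearest-centroid raster of GN element images is piecewise constant.
* The amplitude-SNR convention (20 log10) is assumed for the noise sweep;
  the source's dB convention is not stated.
* No electrode-position or boundary-shape perturbations (listed as future
  work in the source material as well).
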