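# Methods

`cryofield` reconstructs a 3D scalar density from cryo-EM particle
images with known poses and CTFs by fitting a trainable real-space
density field end to end through a differentiable model of image
formation.  This note records the model, its assumptions, the numerical
choices, and what the synthetic benchmarks do and do not demonstrate.

## Image-formation model

A particle image is modeled as

    y = PSF * P_z[ f_theta(R^{-1} x + (-t_x, -t_y, 0)) ] + eps,
    eps ~ N(0, sigma^2 I)

where `f_theta` is the density field in a canonical frame, `R` in SO(3)
and `(t_x, t_y)` are the particle's pose, `P_z` is orthogonal projection
along the viewing axis, and the point-spread function acts as
multiplication by the contrast transfer function (CTF) in Fourier space.
The weak-phase / projection approximation is assumed throughout: no
multislice scattering, no thick-specimen effects, no dose or motion
envelopes beyond an optional global B-factor.

Poses and CTF parameters are inputs, never estimated.

### Grids and discretization

The field is queried on an axis-aligned grid in the microscope frame:
one point per image pixel in-plane (at pixel centers,
`(i - n/2 + 0.5) * pixel_size`), and `n_z` depth samples spanning the
same physical range as the pixel centers.  `n_z` is decoupled from the
box size; 64 or 128 are typical, and small boxes in this package's tests
use `n_z = n`.  Rather than rotating the density, the grid is moved:
each point becomes `R^{-1} p + (-t_x, -t_y, 0)`.  The grid-index to
pixel association is pose-independent, so the projection is one fixed
sparse 0/1 matrix `M` (each grid point contributes to exactly one
pixel), built once per grid and reduced to the surviving columns under
masking.  Projection is a single sparse mat-vec and conserves mass
exactly.

One deliberate deviation from a conventional lattice: the depth samples
span the *point span* `(n-1) * pixel_size` rather than the box edge, so
`n_z = n` reproduces the cubic voxel lattice exactly and a single depth
sample degenerates to the central plane.

### CTF

The CTF uses the standard parametric form with astigmatic defocus,
spherical aberration, amplitude contrast and optional phase shift:

    chi(g) = pi lambda |g|^2 df(theta) - (pi/2) Cs lambda^3 |g|^4 + phi
    CTF(g) = sqrt(1 - A^2) sin(chi) + A cos(chi)

with `df(theta)` the elliptical defocus.  The overall sign is chosen so
`CTF(0) = +A` (positive density yields positive contrast); this equals
the RELION/CTFFIND convention up to a global sign, which is equivalent
to the sign convention of the density itself.  On an even-sized FFT
lattice the Nyquist row represents +/-0.5 cycles ambiguously, which
breaks `CTF(-g) = CTF(g)` there under astigmatism; since a real image
has a Hermitian spectrum, the effective real-to-real operator is
multiplication by the even part of the filter, and `ctf_array`
symmetrizes explicitly.  The resulting operator is linear and
self-adjoint, which the backward pass exploits.

### Jittering

Before querying the field, every grid coordinate is perturbed by an
independent Uniform(-J/2, J/2) draw (fresh draws every forward pass;
J = 0 disables).  In expectation this convolves the field with a width-J
top-hat per axis — a sinc multiplication in Fourier space — acting as a
low-pass regularizer against noise overfitting without ever filtering
the data.  The equivalence is verified by Monte-Carlo tests against the
closed-form top-hat convolution of an analytic signal.

## Density parametrizations

All fields map the canonical box to `[0, 1]^3` by one affine map and are
trained by the package's own reverse-mode gradients (numpy throughout;
every backward pass is finite-difference-checked in the test suite).

**Multi-resolution hash grid** (the flagship).  L = 8 levels with
per-axis resolutions growing geometrically from `base_resolution` (16)
to a finest resolution matched to the Nyquist limit of the data (n/2
cells for an n-pixel box).  Each level stores F = 2 learnable features
per table row; levels whose dense corner lattice fits in the
`2^log2_hashmap_size` budget are indexed directly (collision-free),
larger levels through the instant-NGP spatial hash (coordinates times
the primes 1, 2654435761, 805459861, XOR-combined, modulo table size).
Collisions are resolved implicitly by gradient averaging.  The 8
surrounding corners are blended trilinearly, per-level vectors are
concatenated (length LF = 16), and a 2-hidden-layer ReLU MLP (64 or 128
neurons) decodes a scalar.  Out-of-box queries clamp to the boundary.
Hash tables initialize Uniform(-1e-4, 1e-4), so a fresh field is
near-zero but not degenerate.

**Voxel baseline.**  A dense trainable `n^3` array, trilinear
interpolation, zero outside the box.

**Frequency baseline.**  8 octaves of sin/cos per axis into the same MLP
shape — the classical positional-encoding neural field.

Only a single MLP decoder is used per field.

## Losses

All three objectives derive from the per-pixel i.i.d. Gaussian noise
model; batches sum per-particle losses.

* **MSE**: `sum (y - yhat)^2 / (2 sigma^2)` — the plain negative
  log-likelihood at known sigma.
* **CC** (the default, with sigma = 3): the squared distance between the
  *standardized* images, `(1/(2 sigma^2)) sum (w(y) - w(yhat))^2` with
  `w(x) = (x - mean)/std`; equal to `(n^2/sigma^2)(1 - r)` for Pearson
  r, hence invariant to global scale and offset of either image, with
  sigma a pure constant factor.  Preferred because empirical intensity
  scales are arbitrary.
* **BioEM**: the Gaussian likelihood marginalized analytically over a
  global scale N and offset mu of the prediction, with sigma removed by
  a 1-D saddle point.  Under flat priors this marginalization is
  minimized by driving `||yhat||` to zero — an instability under
  end-to-end training — so the marginalization is performed under
  Gaussian priors N(1, s^2) on the scale and N(0, s^2) on the offset
  (s = 10 by default: broad, centered at a numerically stable nonzero
  scale).  The loss depends on the images only through n^2, sum y,
  sum yhat, sum y^2, sum yhat^2, sum y.yhat; the saddle point is found
  by bounded 1-D minimization over log sigma^2 (floor 1e-6 to keep the
  perfect-fit limit finite), and the gradient follows from the envelope
  theorem at fixed sigma*.  In the wide-prior limit its ranking of
  positively correlated candidate images coincides with the CC loss, as
  both marginalize the same nuisances; for anti-correlated candidates
  the marginalized (sign-free) scale and the sign-fixed CC ranking can
  legitimately differ.

## Heterogeneity by bending space

Conformational variability is modeled by warping the *query
coordinates*, not by moving mass: a reverse mapping.  A shared
(amortized) encoder maps each image to a coarse canonical displacement
field of shape `(3, n_F, n_F, n_F)` (default n_F = 8), which is
trilinearly interpolated at that particle's
posed, jittered grid points and added to them before the density query.
Because the canonical field is pose-independent and only its sampling
points are pose-specific, the per-image deformation is SE(3)
equivariant; with the field forced to zero the pipeline reproduces the
homogeneous model bit for bit.  Smoothness is supplied by the coarseness
of the lattice itself (nearby points share corners); no explicit
regularizer is added.

The encoder is deliberately small: per-image standardization, fixed
average-pooling to about 16 x 16, one ReLU hidden layer (128), and a
linear head reshaped to the field, zero-initialized so training starts
at the homogeneous model.  At these box sizes a fully connected encoder
has ample capacity, keeps the hand-written backward pass simple, and
satisfies the identity-initialization contract exactly.

### The deformation gauge

A constant (image-independent) warp can be traded between the scalar
field and the deformation network with no effect on any rendered image,
so the shared component of the predicted fields is a gauge degree of
freedom that drifts during training and would swamp a cosine-similarity
analysis.  Three measures pin it down:

* the head has no bias term (a purely shared channel);
* AdamW applies decoupled weight decay (default 0.1) to the encoder
  only — the restoring force that migrates shared deformation into the
  scalar field, where it belongs (strong enough to pin the gauge, weak
  enough not to crush the image-conditional signal);
* state analysis operates on *centered* fields: the mean over the
  analyzed set (or the training-time EMA buffer, for streaming use) is
  subtracted, leaving each image's deviation from the consensus
  conformation.

State assignment computes the cosine-similarity matrix of the flattened
centered fields and clusters it spectrally (precomputed affinity
`(S+1)/2`, fixed seed, user-supplied k); the label permutation is
resolved against ground truth by Hungarian matching before computing
classification metrics.

## Synthetic data

The simulator is first-class: densities are Gaussian mixtures at
pseudo-atom ("bead") coordinates, evaluated *analytically* at the posed
grid points and pushed through the very same projection and CTF
operators used in training — so simulation and inference share one
forward model by construction.  Per-pixel i.i.d. Gaussian noise is
added last.

Defaults define the study conditions:

* bead width 2.5 A (residue-scale pseudo-atoms), compact clusters drawn
  in a ball of 0.55 x box radius;
* poses Haar-uniform over SO(3) (via random quaternions); in-plane
  shifts zero unless configured;
* defocus uniform in 8000-20000 A with mild astigmatism, 300 kV,
  Cs 2.7 mm, amplitude contrast 0.1;
* homogeneous benchmark noise sigma = 3 with bead amplitudes calibrated
  (`calibrate_amplitude`) so the mean SNR — clean-signal pixel variance
  over sigma^2, summarized as mean +/- std over images — sits at the
  0.05 operating point;
* the two-state fixture uses wider beads (4 A, a coarse-grained
  residue-cluster scale whose smooth density supplies the long-range
  gradients deformation learning follows) and swings the bead cluster
  furthest along +x (about half the beads) by a 120 degree hinge
  rotation about an axis at the domain boundary: a large-scale
  two-conformation domain motion, run at high signal (sigma = 0.1); the
  shipped benchmark omits CTF corruption so it isolates conformation
  inference from optics inversion.

Ground truth (poses, CTFs, state labels, per-state volumes) is carried
in RELION-dialect STAR metadata plus MRC volumes; numeric labels
round-trip the text format bit-exactly.

What the simulator does *not* emulate: structural noise, ice and
detector statistics, dose damage, motion blur, pose/CTF estimation
error, junk particles.  Synthetic success therefore demonstrates the
correctness and capacity of the estimator under its own noise model,
not performance on empirical micrographs.

## Validation

Fourier shell correlation uses unit-voxel radial shells of the 3D DFT
(rounded integer radius; DC is shell 0) and reports
`Re(sum F_A conj F_B) / sqrt(sum |F_A|^2 sum |F_B|^2)` per shell.
Resolution is the reciprocal of the first frequency at which the curve
drops to a threshold (0.5 against a reference, 0.143 between
half-maps), linearly interpolated between shells, never finer than
2 x pixel size; a curve that never crosses returns the Nyquist limit
with a flag.  No masking or phase-randomization correction is applied
to FSC curves.  A caution surfaced by the half-map workflow: two fields
sharing a strong inductive bias can correlate with each other before
they correlate with the truth, inflating early half-map FSC — prefer
FSC to a reference when one exists.  Real-space agreement uses Pearson
correlation over (optionally masked) voxels.  Classification metrics
(accuracy, sensitivity/recall, specificity, precision) are reported in
percent, rounded to two decimals.

## Training

AdamW with split learning rates: 1e-2 for hash tables, 1e-3 for MLPs,
5e-3 for the deformation encoder (plus its 0.5 decoupled decay).  Batch
size 1 by default — streaming updates, one optimizer step per particle,
matching the one-epoch regime the method is designed for; jitter draws
are consumed in deterministic order from a single run seed, so loss
trajectories reproduce exactly.  A configurable fraction (default 5%)
of particles is held out and evaluated every 100 steps.  Checkpoints
embed the field configuration and round-trip bit-identically.

## Problem sizes in the shipped benchmarks

The test suite and acceptance script run desk-scale versions of the
full-scale protocols: 32-pixel boxes with 200 particles for homogeneous
reconstruction (FSC_0.5 resolution improving several-fold over the
initialized field within one streaming epoch), 24-pixel boxes with
200 + 200 particles for two-state heterogeneity (two homogeneous
warm-up epochs, then eight joint epochs with cosine learning-rate decay
to 5%), and 16k-entry hash tables.  These sizes were chosen so each protocol completes in minutes
on one CPU while leaving the phenomena of interest measurable; they are
scaled-down study conditions, not tuning targets.

## Known limitations

* Pose and CTF are consumed, never refined; errors in them propagate
  directly into the density.
* The BioEM saddle point floors sigma^2 at 1e-6, so the exact-equality
  limit is finite rather than divergent.
* Heterogeneity inference at desk scale is visibly pose-entangled: the
  within-state vs between-state similarity gap is robust, but per-image
  state assignment degrades for views that project the two
  conformations onto similar images.
* Spectral clustering needs k supplied; no model selection over the
  number of states is attempted.
* Masks are consumed (soft masks thresholded at a configurable cutoff,
  zero by default), never created.
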