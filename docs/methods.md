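# Methods

This note describes the models implemented in `covrf`, the conventions and
numerical choices behind them, and what the synthetic data generator does
and does not emulate.

## Spatio-temporal receptive-field model

A receptive field is modelled as a separable spatio-temporal kernel

    T(x, t; Sigma, tau, v) = g(x - v t; Sigma) * h(t; tau),

where `g` is a two-dimensional Gaussian with positive-definite covariance
`Sigma` (px^2), `v` is an image velocity (px/timestep) and `h` is a
time-causal temporal window of scale `tau`.  Convolving a video with `T`
yields a spatio-temporal scale-space representation `L`.

The representation is *covariant* under the three transformation families
that dominate natural video, in the sense that transforming the input and
transforming the kernel parameters commute:

| transformation            | input map            | parameter map            |
|---------------------------|----------------------|--------------------------|
| spatial affine            | x' = A x             | Sigma' = A Sigma A^T     |
| Galilean (velocity) shift | x' = x + u t         | v' = (A v + u) / S_t     |
| temporal scaling          | t' = S_t t           | tau' = S_t^2 tau         |

`covrf.covariance` verifies each identity numerically rather than
symbolically: the matched arm should deviate only by
discretization/interpolation error, and deviations must shrink under grid
refinement, while a deliberately mismatched control arm is at least an
order of magnitude worse.

### Spatial kernels

`covrf.spatial` implements scale-normalized affine Gaussian directional
derivative kernels

    T_{phi^m1 perp-phi^m2, norm}(x; Sigma)
        = sigma_par^m1 sigma_perp^m2 d_phi^m1 d_perpphi^m2 g(x; s Sigma),

with the derivative directions along the eigendirections of `Sigma`
(orientation `phi` and its orthogonal complement) and scale normalization
with gamma = 1 (an m-th order derivative is multiplied by sigma^m so that
peak responses to self-similar structure are scale-independent; the suite
checks constancy to within 2% across sigma in {1, 2, 4, 8} px).

Discretization: the continuous Gaussian is sampled on a supersampled grid
(default 81x81 covering the 9x9-px mask footprint, i.e. 1/9-px sampling);
derivatives are realized by 3-point central differences on that grid
(compact derivative masks applied to the smoothed kernel, not analytic
Hermite sampling); the grid is block-averaged down to the 9x9 mask.  After
downsampling, a zeroth-order mask is rescaled to unit sum, and derivative
masks have their DC component removed.  The DC removal matters for the
large-scale masks: a sigma = 8 px Gaussian truncated to a 9x9-px footprint
leaves a boundary residue that would otherwise violate the zero-sum
property of a derivative kernel.

The default bank used for network initialization contains 144 kernels: the
Cartesian product of 4 orientations (linear on [0, pi)), 4 scales
(sigma_par in {1, 2, 4, 8} px), 3 skews (eigenvalue ratios
lambda_perp/lambda_par in {1, 1/2, 1/4}) and 3 derivative configurations
(first order along phi, first order along perp-phi, and the mixed second
order).  The factorization is a design choice: the combination
4 x 4 x 3 x 3 reproduces the documented bank size of 144 exactly, and
orientation already spans the absolute-axis first derivatives, so separate
x/y derivatives would be redundant.  The zeroth-order kernel is available
through the configuration but not part of the default bank.

### Temporal kernels and neurons

Time-causal temporal smoothing uses the truncated exponential kernel
`h_exp(t; mu) = (1/mu) exp(-t/mu)` for t > 0 (the canonical class of
time-causal scale-space kernels).  Convolution with `h_exp` is identical
to the leaky integrator `mu du/dt = -u + I`; a bank of K such filters with
time constants on a geometric series `tau_k = c^(2(k-K)) tau_max`
(`tau = mu^2`, default c = sqrt(2)) covers logarithmically spaced temporal
scales and is covariant to temporal scaling.

For the network's scale channels the time constants are logarithmically
spaced with *pinned endpoints* on [1, 4] timesteps (ratio 4^(1/(K-1))),
i.e. {1, 4^(1/3), 4^(2/3), 4} for K = 4.  The pure geometric series with
c = sqrt(2) and mu_max = 4 would give mu_min = sqrt(2), not 1; the
endpoint-pinned reading of "log-distributed on [1, 4]" wins, and both
spacings are available (`geometric_time_constants`, `log_time_constants`).

Discrete updates use the exponential-Euler scheme

    u <- u exp(-dt/mu) + (1 - exp(-dt/mu)) I,

exact for piecewise-constant input and unconditionally stable.  It makes
the retention identity exact: with mu = 2, an impulse decays to
exp(-8/2) = 0.0183 of its amplitude after 8 unit timesteps (the
motivation for giving the multi-frame ReLU baseline 8 frames of history).
For smooth inputs the scheme is first order: the L-inf deviation from the
exact `h_exp` convolution empirically shrinks by a factor approaching 2
per halving of dt (the suite asserts a factor > 1.9).

The leaky integrate-and-fire (LIF) neuron adds a Heaviside threshold
(theta_thr, default 1) with reset to theta_reset (default 0).  The Spike
Response Model (SRM) closed form replaces the jump by a linearized reset
kernel `eta(t - t_f; mu_r) = -theta_thr exp(-(t - t_f)/mu_r)`.  Two
identities about the reset are worth stating precisely, because they are
easy to over-read:

* with mu_r equal to the *membrane* constant mu, the SRM evaluated on the
  LIF's own spike train reproduces the instantaneous-reset membrane
  exactly (resetting u to zero is the same as subtracting theta_thr
  through the membrane filter);
* as mu_r -> 0 the reset becomes instantaneous in the sense that the jump
  at the spike is the full -theta_thr and its after-effect vanishes
  immediately; it does *not* mean the mu_r -> 0 SRM and the
  instantaneous-reset LIF emit identical spike trains under sustained
  suprathreshold drive (the vanished reset trace lets the SRM re-fire
  every step there).

Simulated LIF runs (`lif_run`) locate threshold crossings inside an
integration step by linear interpolation and start the reset trace at the
interpolated time; this keeps per-spike timing errors at O(dt^2), which
the temporal-scale-covariance check (matched spike times within
2 * fine_dt at fine_dt = 1e-3) requires over trains of dozens of spikes.

### Numerical verification choices

Warping uses bilinear interpolation with edge clamping; comparisons
exclude a boundary margin of 3 x the largest post-transport standard
deviation.  Time rescaling of sampled signals uses linear interpolation on
the fine grid (default fine_dt = 1e-3).  The deviation metric is relative
L-infinity over the valid region; spike trains are compared by sorted
(greedy nearest-time) matching.  The joint demonstration grows three
squares exponentially at velocities {0.0066, 0.0132, 0.0264} /step over 75
steps (final sizes differing by 4x), analyzes each with a spatial scale
matched to its current size and a time constant inversely proportional to
its growth velocity, and compares the traces on a common normalized time
axis; pairwise Pearson r > 0.9 is the package's own proxy criterion, since
the underlying claim ("identical in the continuous case") is qualitative.

## Event simulator

The simulator emulates an event camera watching thin shape contours
(triangle, square, circle; 1 supersampled-pixel stroke).  Rendering runs
at 8x the dataset resolution (2400^2 for 300^2 frames) for sub-pixel
accuracy and is area-averaged down (the antialiased form of bilinear
reduction; plain 4-neighbour bilinear subsampling at 8x would lose the
contours entirely).  Events are produced per pixel by integrating
successive frame differences until they cross a contrast threshold,
emitting ON/OFF polarity events — the standard event-camera generation
model.  Ground truth is the sub-pixel center trajectory of each shape,
0-based, x rightward, y downward, clamped to [0, resolution).

Conventions and calibration (fixed once, then frozen):

* **Motion coupling.** Each temporal-kind movie has one velocity parameter
  with magnitude log-uniform on [0.16, 1.28] px/step; it sets both the
  signed scale velocity (size change per step, sign random per shape,
  sizes clamped at 2 px) and the translation speed (uniform random
  direction per shape).  This makes the velocity parameterize the movie's
  sparsity, which is the documented behaviour of the dataset.
  Spatial-kind movies have static sizes (log-uniform [10, 80] px) and draw
  translation speeds from the same log-uniform velocity distribution.
* **Threshold.** The contrast threshold defaults to 0.15 of full contour
  intensity (the 1-px stroke downsamples to about 1/8 intensity, so the
  threshold is slightly above one contour pass; the accumulator lets slow
  motion integrate across frames).  Together with temporal-kind starting
  sizes log-uniform on [40, 90] px, this calibration reproduces the
  documented activity levels: about 1 per-mille active pixels at velocity
  0.16 px/step and about 3 per-mille at 1.28 px/step (including noise).
* **Noise.** Background noise is Bernoulli per pixel *per movie* at
  5 per mille: each pixel fires at most one noise event of random polarity
  at a uniformly chosen frame.  Read per-pixel-per-frame instead, 5
  per-mille noise alone would exceed the documented total activity of the
  slowest movies by a factor of five; the per-movie convention keeps the
  noise floor at ~0.1 per mille per frame and makes the activity levels
  attainable.  The per-frame convention remains selectable.
* Determinism: one master seed spawns per-movie child seeds through
  `numpy.random.SeedSequence`; regeneration is byte-identical.

What the generator does not emulate: real event-camera noise statistics
(hot pixels, refractory periods, per-pixel threshold mismatch), textured
backgrounds, occlusion, and illumination changes.  Tests passing on this
data show that the pipeline and the initialization effect behave as
designed under idealized sparse stimuli; they do not certify performance
on recordings from physical sensors.

## Scale-channel tracking network

Four convolutional blocks; blocks 1-3 are replicated across K parallel
temporal scale channels (channel k's temporal activations use mu_k from
the endpoint-pinned series), block 4 concatenates all channels and merges
them with a 1x1 convolution into one activation map per tracked shape.
Per block: spatial convolution (no bias) followed by a temporal
activation — leaky integrator + ReLU (LI variant), LIF with fast-sigmoid
surrogate gradient of slope 10 and detached reset (LIF variant), or plain
ReLU (frame-based baselines; the multi-frame baseline sees the last 8
frames stacked in channels).  The coordinate head temporally smooths the
merged maps with a leaky integrator in *all* variants and reads out one
(x, y) per shape with a differentiable spatial average.

Coordinate head weighting: the default is mass normalization — rectify the
map, add a small uniform epsilon, and take the normalized centroid.  The
centroid is invariant to overall activation amplitude, which matters for
extremely sparse inputs whose network activations are orders of magnitude
below one; a spatial softmax at temperature 1 (available in the
configuration) is essentially flat at those amplitudes and provides no
usable gradient.  The epsilon doubles as a graceful fallback: an empty map
predicts the frame center.  With 'same'-style padding, map cell i is
centered on input pixel i times the product of the strides; the head's
outputs use that mapping.

Initialization: blocks 1-2 take their spatial weights from the kernel bank
(block 1 exactly, tiled over the two polarities; block 2 tiled over the
fan-in and scaled by 1/fan_in), channel time constants come from the
endpoint-pinned series, and the block-3 and head time constants are fixed
to the fastest constant.  Blocks 3-4 are uniform random in both schemes.
The uniform control draws blocks 1-2 uniformly between the minimum and
maximum weight value the receptive-field initialization would place in
that layer, and time constants uniformly on [mu_min, mu_max] — "white
noise in the same parameter domain".

Training: backpropagation through time over all 50 frames (hand-derived
reverse-mode gradients through the exponential-Euler scans and im2col
convolutions), Adam with learning rate 1e-3 (free parameter; the source
experiments do not pin it), batch 16, mean per-frame Euclidean distance in
px as the loss.  The time constants are trainable parameters, floored at
0.1 timesteps.  The binary event input never changes across epochs, so the
first convolution is driven by a per-movie cached sparse im2col matrix —
an exact reformulation that makes CPU training of the sparse-input models
practical.

## Effect size

The initialization effect is quantified as Cohen's d: the difference of
the two groups' mean losses divided by the pooled standard deviation with
(n_i - 1) weights.  The alternative (n_2 - 2) second-group weight that
sometimes appears in print is treated as a typographical slip of the
standard formula but remains available behind a flag.  Improvement
percentages are (l_uniform - l_init)/l_uniform x 100 on final validation
losses.

## Desk-scale initialization study

The full-scale study (300x300 movies, 4 scale channels, 144 kernels per
block, 5 runs per condition) takes hours of CPU; `covrf.experiments`
defines a desk-scale variant that keeps the experiment's structure intact
at 64x64 resolution: 2 scale channels, an 8-kernel bank (2 orientations x
2 scales, first-order derivative pairs), 5x5 masks in blocks 2-3, strides
(4, 2, 2), 200 three-shape spatial-kind movies with all sizes and
velocities scaled proportionally to the resolution, batch 16, Adam 1e-3,
20 epochs.  Following the design of the source experiment, *one* dataset
is generated (data seed 0) and both initialization schemes are trained
five times on identical data and batch orders, varying only the
model/training seed; each run compares final validation losses.  The
one-dataset/many-runs structure matters: regenerating the dataset per run
adds dataset-difficulty variance of the same order as the initialization
effect itself at this scale.  At desk scale the effect is a modest but
consistent final-loss advantage (and a visibly earlier training
breakthrough); the published effect sizes belong to the full-scale
configuration.

## Known limitations

* The NumPy implementation targets clarity and CPU practicality, not
  large-scale training; the full 300^2, 144-kernel configuration builds
  and runs forward passes but is not meant to be trained here.
* Batch normalization (optional flag, off by default everywhere) inserts a
  stateless per-feature-channel standardization over batch, time and space
  before each temporal activation — the train-mode behaviour of framewise
  batch norm.  Because the statistics pool over the time axis, a
  normalized forward pass is not frame-causal; no claims are made about
  its interaction with the initialization schemes.
* Velocity-adapted spatial smoothing appears only in the covariance
  verification; the trained networks use v = 0 kernels.
* The desk-scale study demonstrates the direction of the initialization
  effect, not the published effect sizes; the full-scale quantities
  (pixel-level L2 losses, improvement percentages, Cohen's d >= 1.6-1.9)
  require the original compute budget.
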