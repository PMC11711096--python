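# Methods

This note documents the models, estimators and synthetic benchmarks
implemented in `retpop`, the choices made where the design was genuinely
open, and what the synthetic experiments do and do not establish.

## Scope and data model

The package analyses populations of retinal ganglion cells (RGCs) responding
to gaze-shifted naturalistic videos, flashed/flickering sinusoidal gratings
and checkerboard white noise.  Responses are binned spike counts
(`SpikeRaster`, trials x bins, half-open bins left-aligned to frame onsets);
stimuli are Weber-contrast frames with pixel pitch in um/pixel
(`StimulusSet`).  Coordinates are x rightward, y downward, origin at the
image centre; all model geometry is in micrometres on the retina.

## Analytic DoG grating response

A difference-of-Gaussians receptive field is a unit-integral elliptical
centre Gaussian minus `w_surr` times a unit-integral surround whose widths
are scaled by `k_s` (constraints: sigma > 7.5 um, |theta| < pi/4,
1 < k_s < 6, 0 <= w_surr < 1).  Its inner product with a grating
`sin(2 pi f (x cos th + y sin th) + phi)` is `A(f) cos(Theta)` with

    A(f)  = exp(-2 pi^2 sigma_eff^2 f^2) - w_surr exp(-2 pi^2 (k_s sigma_eff)^2 f^2)
    sigma_eff^2 = sigma_x^2 cos^2(th + th_DoG) + sigma_y^2 sin^2(th + th_DoG)
    Theta = 2 pi f sqrt(x0^2 + y0^2) cos(th - atan2(y0, x0)) + phi - pi/2.

Two amplitude conventions are shipped.  The default exponent `2 pi^2` is the
exact Fourier transform of a unit-integral Gaussian and is validated against
fine-grid pixel-space quadrature to < 1e-3 relative error; an alternative
convention with exponent `2 pi` is selectable (`mode="printed"`) for
compatibility with parameter values quoted under that convention.  The phase
uses `atan2`, which handles every quadrant of the centre offset; a centred
field reduces to `phi - pi/2`.

## DoG LN fitting

`R = a N(beta r_DoG + gamma)` with a logistic `N`; all ten parameters are
fitted by constrained maximum likelihood (Poisson negative log-likelihood,
L-BFGS-B, each presentation entering independently).  Fitting is staged:
the surround is pinned off first and then freed.  A free surround from a
generic start reliably falls onto a degenerate near-cancellation ridge
(`k_s -> 1`, `w_surr -> 1`, inflated sigma) whose likelihood beats poor
starts; the staged fit recovers sigma within a few percent and the centre
within ~2 um at 1e4 flashes in the recovery benchmark.

## Subunit-grid model

`R_SG = G( sum_s w_s N(beta r_s + gamma) )`: 1,200 candidate circular-DoG
subunits on a hexagonal lattice spaced 16 um around the cell's (DoG-fitted)
centre, shared subunit shape (sigma, k_s, w_surr) and logistic nonlinearity,
non-negative weights, Naka-Rushton output `G(x) = a x^n/(x^n + k^n) + b`
(the baseline `b` exists only in the flashed variant).  The cost is the
spike-normalized negative log-likelihood plus a density regularizer
`lambda sum_s w_s sum_{i != s} w_i / d_si^2` that penalizes crowded
non-zero weights.

Numerical choices:

- **Regularizer units.**  Pairwise distances enter in grid-spacing units
  (nearest neighbours contribute 1/1).  With distances in um the standard
  ladder `lambda = 1e-6 .. 5e-4` is numerically inert at the natural weight
  scale (penalty ~1e-5 against per-spike likelihood differences ~1e-3);
  in grid units the ladder spans weak-to-strong and the surviving subunit
  count decreases along it, which is the behaviour the ladder exists for.
- **Optimization.**  Minibatch ADAM (batch 64, beta1 0.9, beta2 0.999,
  eps 1e-6), epochs = 4e5 / N_presentations, Gaussian learning-rate
  schedule (mean N_ep/2, SD N_ep/5), projection onto the constraint set
  after every step.  The peak learning rate for flashed fits is 0.02 (the
  same value as the spatiotemporal fits); at lower peak rates the
  stochastic stage equilibrates in a diffuse-weights valley whose
  regularized cost is measurably worse than the sparse optimum.
- **Polish.**  After ADAM, a deterministic full-batch L-BFGS-B refinement
  with analytic gradients runs on the same regularized cost, restricted to
  weights above 1% of the maximum.  Because the subunit threshold `gamma`
  lies in a soft likelihood direction (it trades off against `beta`,
  `w_surr` and the output stage), the polish is multi-started from several
  rescaled thresholds — weights rescaled to preserve the mean pool drive —
  and the best cost wins.  Likelihood decides; no start is privileged.
- **Pruning.**  Weights below 5% of the maximum are zeroed; a 2-D Gaussian
  (weighted moments, plus sigma^2 I for subunit extent) is fitted to the
  weight-summed receptive field and subunits beyond 2.5 SD are zeroed; the
  output stage plus a global weight scale are then refitted.  The
  polish/prune round is applied twice.
- **Selection.**  Six models over the lambda ladder; eligibility requires
  at least three subunits and coverage < 3; among eligible candidates the
  BIC `N_sub ln(N_data) - 2 ln L` decides for flashed fits and the training
  log-likelihood for natural-video (flicker-fitted) models; ties go to the
  smaller lambda.

Parameter characterization: coverage = 4 sigma over the weighted mean
nearest-neighbour distance (undefined below three subunits); nonlinearity
asymmetry = (1 - M)/(1 + M) where M is |min| of the offset-and-scaled
logistic on [-1, 1] (0 = odd-symmetric, 1 = fully rectifying).

**Identifiability.**  Predictions are the primary recovery target; among
parameters only sigma, the centre and the asymmetry are treated as
interpretable.  In the recovery benchmark (7 subunits of sigma 15 um on a
32-um sub-lattice, rectifying logistic beta 4 / gamma -2, gently saturating
output, 1,200 gratings x 5 trials) the selected model recovers sigma within
~15%, asymmetry within ~0.15 and held-out rates at R^2 > 0.99.  With 1-2
trials per grating the asymmetry is *not* identifiable to that precision:
even a maximum-likelihood refit started at the generating parameters drifts
~0.14 below the true asymmetry along the soft direction.  Five trials per
grating (the upper end of common practice for flashed batteries) is the
benchmark's stated condition.

## Spatiotemporal variants

Temporal integration over 500 ms uses ten basis functions: two single-frame
boxcars on the two frames immediately before the response bin and eight
raised cosines with peaks spanning 0-250 ms.  Centre and surround histories
(`r_C`, `r_S`, unit-integral Gaussians; the surround's sign and strength
live in its temporal coefficients, so only the product `w_surr x k_St` is
identifiable and no extra constraint is imposed) are projected on the basis;
the DoG LN variant is fitted by L-BFGS-B, the subunit-grid variant by the
same ADAM machinery with batch 2,000 and peak rate 0.02.  The history window
ends at the response bin's start.

## Receptive-field characterization

STA over a 500 ms (configurable) lag window; temporal filter = mean time
course of stixels whose absolute peak exceeds 4.5 robust SDs (1.4826 x MAD)
of all STA elements, unit-normalized with positive extremum; spatial filter
= projection of the STA onto it.  Contours: bilinear upsampling to
single-pixel resolution (image-resize semantics so the um-per-pixel factor
is exact), circular Gaussian blur of sigma 4 upsampled pixels (the blur
scale is configurable since the reference scale is ambiguous), marching
squares at 25% of the maximum, keep the contour enclosing the peak, triage
points whose neighbour gaps both exceed 20 robust SDs of all gaps; centre =
coordinate-wise median of contour points, area by the shoelace formula.

## Information rates and fractional redundancy

Spike trains binned at 0.4 ms are cut into 0.8-s sections (2,000 bins,
1.25 Hz resolution, DC excluded, 200 Hz cutoff, unnormalized DFT — any
constant cancels in the signal-noise difference, asserted by test).  Signal
(noise) entropies use coefficient covariances over sections (trials)
averaged over trials (sections); information rate = entropy difference
summed over frequencies divided by the section length; fractional
redundancy `C = (I_i + I_j - I_ij)/min(I_i, I_j)`.

Two entropy conventions are shipped because the sum-inside-the-log pair
formula is not additive over independent cells: in that convention two
independent cells with identical statistics receive C = 1.  The default
`det` mode uses full Gaussian entropies (sum of log eigenvalues), which is
additive for independent cells (C -> 0) and approaches C -> 1 for
duplicated signals with independent noise as SNR grows; the `printed` mode
is retained behind a flag and satisfies the duplicated-raster identity
I_pair = I_single exactly.  Note the det-mode duplicated-signal limit is
approached only at high per-frequency SNR (the second noisy copy genuinely
adds up to one bit per mode), so the contract fixture uses a strongly
modulated high-rate signal.  Degenerate (zero) variances are reported as
-inf sentinels, never clipped; a noise-free response yields an infinite
rate with the sentinel visible.

## Fixations, spatial contrast and correlation decompositions

Saccades are detected as local maxima of the instantaneous gaze speed
(displacement between consecutive positions times frame rate) above a
deg/s threshold converted through the retinal magnification (100 um/deg
primate, 31 um/deg mouse); peaks closer than the minimum interval keep only
the taller (SciPy's peak `distance` rule); image transitions always split.
Spatial contrast is the weighted SD of frame pixels with the positive part
of the normalized receptive-field profile as weights; per fixation, medians
over frames.  The high/low contrast split sorts fixations by pair-averaged
linear activation, pairs neighbours (an odd trailing fixation is dropped)
and assigns the higher-contrast member of each pair to the high group, so
mean activation stays balanced.  Partial correlations split the Pearson
numerator over frame subsets with global means/SDs, making the
decompositions exact by construction.  Maximally differentiating fixations
rank fixations by the two models' mean absolute prediction difference
normalized by each cell's response range, averaged over the pair — the
responses never enter the selection; the top 20% (ceil) and a half/half
nonlinear/linear split are reported, ties broken by fixation index.

## Synthetic data

All stimuli and responses are generated from seeds (pure functions of
configuration + seed; per-cell/per-trial substreams are derived so adding
cells never reshuffles existing draws).  Spiking is inhomogeneous Poisson —
matching the fitting assumption — with the rate held constant within each
stimulus frame.

- **Gratings** are parameterized by (f, theta, phi); the standard flashed
  battery uses 25 log-spaced frequencies (half-periods 15-1,200 um), 12
  orientations and 4 phases (1,200 gratings), 200 ms flashes with grey
  gaps.  Flicker batteries update every frame with an interleaved frozen
  segment.
- **Checkerboard** white noise is binary +/-1 at stixel resolution.
- **Natural-like images** are 1/f-spectrum Gaussian noise clipped to
  [-1, 1]; `make_scene_images` additionally draws *independent* low-pass
  ("luminance") and high-pass ("texture") amplitudes per image,
  log-uniformly, mimicking the quasi-independence of local mean luminance
  and local spatial contrast across natural scenes (bright-and-flat sky vs
  mid-grey textured foliage).  This independence is what gives the
  activation-balanced contrast split its discriminative power; in pure 1/f
  images luminance and texture are fully coupled and the split degenerates.
- **Gaze videos** show each image for 1 s with a Gaussian fixational jitter
  (default SD 3 um/frame) and planted saccadic steps (default one per
  image, 150-250 um), applied as nearest-pixel translation with edge
  padding.

The ground-truth population experiment uses two mosaics of four cells
(adjacent pairs 70 um apart): *rectified* cells pool 61 small (sigma 6 um)
band-pass subunits (strong surround, w_surr 0.8) through a steep
high-threshold logistic — a local spatial-contrast detector with sparse,
right-skewed responses — and *linear* control cells are DoG LN models
driven by local luminance in their linear range.  With these encoders the
high-contrast partial correlation exceeds the low-contrast one for
rectified pairs (difference ~ +0.1 to +0.35 across seeds), linear pairs are
balanced, and det-mode fractional redundancy of rectified near pairs
exceeds that of linear pairs.

What these synthetic benchmarks do *not* show: real RGC responses are not
Poisson (fixation-level Fano factors below 1), have temporal receptive
fields the static encoders lack (no fixation-onset transients), and real
scene statistics are richer than two-component 1/f noise.  The benchmarks
validate the estimators and the direction of the mechanism, not
quantitative agreement with any recorded dataset.

## Problem sizes

Default benchmark sizes were chosen so the full suite runs on a single CPU
in minutes: 1,200-grating battery x 5 trials for subunit recovery (six
ladder fits, ~2-4 min), 1e4 flashes for DoG LN recovery, 4,500 checkerboard
frames (~9 x 10^3 spikes) for STA recovery, 50 Monte-Carlo replicates for
the independence contract, and 40-image videos with 30 trials for the
population experiment.

## Known limitations

- The subunit-grid optimizer is stochastic; recovery margins (sigma,
  asymmetry) vary by a few percent across seeds.
- The flashed-variant asymmetry statistic extrapolates the logistic to
  [-1, 1] although grating drives never exceed |1 - w_surr|; it is
  therefore sensitive to the surround-strength estimate.
- The spatiotemporal subunit fit is practical for reduced grids (tens to a
  few hundred sites) at desk scale; the full 1,200-site grid is supported
  but slow in pure NumPy.
- `information_rate` returns +inf (flagged by the -inf noise sentinel) for
  noise-free fixtures; callers must treat it as an estimator ceiling.
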