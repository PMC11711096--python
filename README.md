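# retpop

Models and analyses of redundancy in retinal ganglion-cell (RGC) population
responses to naturalistic, gaze-shifted stimuli.

Under natural viewing, saccades and fixational eye movements shift the whole
retinal image at once.  Whether RGC populations still *decorrelate* their
output under such stimulation — the central prediction of efficient-coding
theory — depends on the nonlinear structure of their receptive fields: cells
that pool many small rectified subunits respond together whenever a fixation
lands on locally high spatial contrast, producing correlated, redundant
spiking.  `retpop` implements, end-to-end and on fully synthetic data with
known ground truth, the computational machinery needed to study this:

- **Stimulus and response simulation** (`retpop.synthkit`): checkerboard
  white noise, flashed and flickering sinusoidal gratings, natural-like
  videos built from 1/f-statistics images displaced by gaze traces with
  fixations and saccades, and Poisson spike trains from known LN /
  subunit-grid encoders arranged in mosaics.
- **Receptive-field characterization** (`retpop.rfchar`): spike-triggered
  averages, robust spatial/temporal filter separation, contour extraction,
  symmetrized R², fixation-wise Fano factors.
- **Parametric grating models** (`retpop.gratmodels`): the closed-form
  response of a difference-of-Gaussians (DoG) receptive field to a grating,

      r_DoG = A(f) cos(Theta),
      A(f) = e^{-2π²σ_eff²f²} − w_s e^{-2π²(k_s σ_eff)²f²},

  the DoG LN model `R = a N(β r_DoG + γ)`, and the subunit-grid model
  `R = G(Σ_s w_s N(β r_s + γ))` — a hexagonal lattice of identical
  circular-DoG subunits with non-negative weights, a shared logistic
  nonlinearity, and a Naka–Rushton output — fitted by minibatch ADAM with a
  density regularizer `λ Σ_s w_s Σ_{i≠s} w_i/d²_si`, pruning, and
  BIC/likelihood model selection over a six-λ ladder.  Spatiotemporal
  variants use a ten-function raised-cosine temporal basis.
- **Natural-stimulus prediction** (`retpop.natpredict`): histogram or
  maximum-likelihood output nonlinearities, explained-variance R², Spearman
  scoring of flashed-image responses, maximally differentiating fixations.
- **Spike-train information** (`retpop.inforate`): frequency-domain signal
  and noise entropies of 0.4-ms-binned spike trains, single-cell and pair
  information rates, and fractional redundancy
  `C_ij = (I_i + I_j − I_ij)/min(I_i, I_j)`.
- **Pairwise correlation structure** (`retpop.paircorr`): saccade detection
  and fixation segmentation, receptive-field spatial contrast, exact
  additive decompositions of pairwise correlations (high/low spatial
  contrast; linear/nonlinear fixations), stimulus pixel correlations,
  decorrelation, and direction-selectivity metrics.

See `docs/methods.md` for the models, estimators, numerical choices and
limitations.

## Worked example

Simulate a rectified-subunit cell pair and a matched linear pair under a
gaze-shifted video, split their correlations by spatial contrast and
measure fractional redundancy:

```python
from retpop import experiments as ex

res = ex.contrast_correlation_experiment(seed=1)
print(res)
```

prints (seed 1):

```
{'rect_r_high': 0.368, 'rect_r_low': 0.214,
 'lin_r_high': 0.135, 'lin_r_low': 0.146,
 'rect_c_frac': 0.123, 'lin_c_frac': 0.071, 'n_fixations': 80}
```

The rectified pair's correlation comes mostly from high-spatial-contrast
fixations (`r_high > r_low`; the two partial correlations sum exactly to
the pairwise Pearson correlation), the linear pair's contribution is
balanced, and the rectified pair carries more redundant information
(`c_frac`) than the linear pair — the signature of nonlinear receptive
fields breaking redundancy reduction under gaze shifts.

The numbered scripts under `analysis/` run the full pipeline and write
tables under `results/`:

```bash
python analysis/01_simulate_population.py 1    # stimuli + mosaics + spikes
python analysis/02_receptive_fields.py 1       # STA, filters, contours
python analysis/03_fit_grating_models.py 1     # DoG LN + subunit-grid ladder
python analysis/04_natural_predictions.py 1    # image/video prediction scores
python analysis/05_information_redundancy.py 1 # information and redundancy
python analysis/06_correlation_decomposition.py 1
```

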