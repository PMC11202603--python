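# Methods

`sonoac` implements an end-to-end synthetic study of AI-enhanced
quantitative-ultrasound attenuation-coefficient (QUS-AC) estimation for
hepatic steatosis: randomized abdominal phantoms with a known liver
attenuation coefficient, a fast plane-wave pulse-echo simulator, a neural
regressor conditioned on the B-mode image, and the clinical agreement and
diagnostic statistics used to validate attenuation-based grading.

## Phantom model

A phantom is a 2-D imaging plane sampled on an axial-by-lateral grid
(default 80 x 40 mm at 0.2 mm cells; the desk-scale profile uses
80 x 32 mm at 0.25 mm).  Its anatomy:

- **Superficial layers.** 6-10 layers fill exactly the top 30 mm: skin on
  top, then a random stack of fat and muscle.  Layer thicknesses are
  proportional random weights bounded away from zero.
- **Liver.** One ellipse with both semi-axes drawn uniformly from
  50-80 mm, centred laterally near the probe axis and vertically so its top
  meets the layer zone.  The liver's attenuation draw is the regression
  ground truth.
- **Vessel-like objects.** 0-9 circles with radii 3-50 mm.  Their centres
  are drawn over a 180 x 240 mm "world" — the full abdominal cross-section
  of an adult at the cohort's mean BMI — and cropped by the imaged grid, so
  a small, realistic fraction of them intersects the view.  Objects this
  large are organs as much as vessels; their lumens scatter weakly
  (x 0.15), which is what makes them dark and recognizable in B-mode.
- **Acoustic properties.** Each region draws speed of sound, attenuation
  (dB/cm/MHz) and density uniformly from published per-tissue abdominal
  ranges (liver 1500-1600 m/s, 0-1.0 dB/cm/MHz, 1050-1150 kg/m^3; see
  `TISSUE_PROPERTY_RANGES`).  Per-cell containment in these ranges is
  asserted by tests over 10,000 sampled phantoms.
- **Speckle.** Fewer than 10 sub-wavelength scatterers per
  wavelength-by-wavelength unit area (wavelength at 3 MHz and 1550 m/s),
  placed uniformly inside each unit cell with densities 800-1200 kg/m^3.
  The per-phantom count (1-9) is drawn once, so the bound holds exactly.
- **Probe-shape warp.** To model a convex array pressed into the abdomen,
  every lateral column is shifted deeper by the probe sagitta
  `R - sqrt(R^2 - x^2)` (default R = 60 mm) as a periodic roll.  This
  conserves per-class cell counts exactly and puts the warped skin surface
  on the probe circle; the sliver wrapped in from the deep edge lies above
  the probe face and outside the insonified region.

Ground truth is the attenuation value assigned to liver-labelled cells.
(The alternative reading — truth derived from an MRI fat-fraction — is
meaningless for a synthetic phantom and is treated as a misstatement of the
source protocol.)

## Forward model

Full pseudospectral simulation is out of scope; the default
`ScattererForwardModel` is a frequency-domain scatterer summation designed
to preserve the one physical quantity the method estimates — frequency-
dependent attenuation along the two-way path — at desk-scale cost:

- Reflectors are the speckle scatterers (reflectivity = relative density
  contrast) plus axial impedance steps between grid cells (specular layer
  and organ boundaries).
- For a steering angle theta, the transmit delay is
  `(z cos theta + x sin theta) / c_bar` and the receive delay the
  element-to-scatterer distance over `c_bar`, where `c_bar` is the mean
  sound speed along the scatterer's axial column.  Amplitude carries 1/r
  receive spreading.
- Attenuation `10^(-alpha f d / 20)` is integrated along the straight
  axial ray (refraction ignored), doubled for the round trip.  Echoes are
  deposited onto a (attenuation-bin, channel, time) lattice — linear
  interpolation in both arrival time and attenuation — and each bin is
  convolved once with the correspondingly filtered pulse in a single FFT
  pass.  48 bins keep the interpolation error below 0.1 dB across the band.
- The pulse is a causal Gaussian-windowed 3-cycle cosine at 3 MHz, sampled
  at 12 MHz (values typical of abdominal convex probes; the source system
  does not report them).  64 channels at 0.3 mm pitch transmit five plane
  waves at -7.2, -3.6, 0, 3.6, 7.2 degrees.
- White receiver noise is added at 60 dB below the full-frame RMS.  Because
  deep echoes sit 40-50 dB below shallow ones (spreading plus attenuation),
  a noticeably smaller SNR buries the deep liver — the signal the method
  reads — under the noise floor.
- Optional first-order reverberation between the probe face and strong
  superficial interfaces (`ProbeConfig.reverb_gain`, default off) adds the
  repeating clutter bands seen in vivo.

What this model deliberately omits: multiple scattering, refraction,
aberration, nonlinear propagation and element directivity.  Two
calibrations pin the attenuation encoding: (1) a point target at 5 cm with
alpha = 0.5 dB/cm/MHz loses exactly 15 dB at 3 MHz relative to a lossless
medium (closed form, evaluated at a single frequency so pulse bandwidth
cancels); (2) an independent multigate spectral-log-difference estimator recovers
known homogeneous attenuations 0.2/0.5/0.8 dB/cm/MHz within 0.1 (power
spectra averaged over channels and angles are gated at a ladder of depths;
the per-frequency dB-per-cm depth slope is linear in frequency with
coefficient `-2 alpha`).

B-mode images are formed by per-angle delay-and-sum on a pixel grid,
coherent compounding, axial envelope detection, log compression and
max-normalization, clamped at a 60 dB dynamic range.

## Network

The regressor mirrors the reference architecture at configurable width:

- **Encoders.** Five independent 1-D convolutional paths (one per steering
  angle) with residual blocks, operating over the time axis of the
  envelope frames; outputs are concatenated channel-wise.
- **BGN.** The fused features are standardized per time slice across
  channels (population sigma, epsilon 1e-5) and re-modulated:
  `X_t = gamma_t (x_t - mu) / sigma + beta_t`, with gamma_t and beta_t
  produced from the B-mode through 4 shared convolutional layers and 4
  separate fully connected layers per parameter.  Default is one
  gamma/beta scalar per slice; per-slice-and-channel vectors sit behind
  `gamma_vector_mode`.  The gamma/beta output layers start at zero
  weights (gamma = 1, beta = 0), so training begins from plain
  normalization and learns modulation gradually.
- **Trunk and head.** 2-D convolutions with batch normalization over the
  (channel x time) feature map, then fully connected layers onto a single
  scalar, passed through a scaled sigmoid onto [0, 1.2] dB/cm/MHz
  (physical range with headroom).
- The ablation variant drops the B-mode branch and keeps gamma = 1,
  beta = 0; it is otherwise identical, so the two differ exactly by the
  B-mode-branch parameters.

Everything runs on a small in-package reverse-mode autodiff engine over
numpy (validated against finite differences); training uses Adam with L1
loss and coupled L2 regularization, early-stopped on validation L1
(patience 20 epochs at full scale, min-delta 1e-4), returning the
best-validation checkpoint.  The full-scale configuration is
8000/1000/1000 records with initial learning rate 5e-6; the desk-scale
profile (see below) uses a higher rate suited to its much smaller network.

Envelope frames are block-averaged to the network input size
(default 32 channels x 128 samples per angle), log-compressed and
mean-centred per record so absolute gain cannot leak the target; B-mode
images are average-pooled to 32 x 32 and rescaled to [0, 1].  During
training, records are randomly mirrored laterally (a symmetry of the
array).  One master seed fans out to phantom geometry, receiver noise,
weight initialization and shuffling.

## Evaluation

MNAE is the mean absolute error normalized by the 1.0 dB/cm/MHz span of
the ground-truth attenuation range, in percent.  (Normalizing by
per-sample truth is undefined at the range's lower bound of 0.)  Every
evaluation reports the mean-predictor baseline — predicting the train-set
mean everywhere — on the same held-out split; for a uniform target this
baseline sits near 25%.

Splits are 8:1:1 by phantom id.  At small n the assignment is stratified:
records are ordered by coarse liver-visibility bins and target value, then
dealt round-robin in shuffled blocks, so no split is systematically harder
than another.  Liver visibility matters because a sampled vessel/organ
object can cover the entire insonified window, making the liver
attenuation unidentifiable for that record; at the desk scale about one
record in seven has under 10% of the deep window showing liver.

## Desk-scale profile and what it shows

The reference study trains on 8000 simulated records; this package's
default protocol ("reduced" profile) uses 400 records (320/40/40), a
0.25 mm grid and a compact network (encoder widths 8/12/16, trunk 12/16),
chosen so the complete pipeline — simulation, both training variants over
three seeds, and all calibration checks — reproduces on a single CPU in
well under an hour.  At this scale the B-mode-guided model reaches an MNAE
of about 11% versus a ~26% baseline.  For comparison, the full-scale reference
full-scale result is 6.49% with a 41% relative improvement over the
no-B-mode ablation — which places that ablation at ~11%: the desk-scale
pipeline reproduces the no-B-mode performance level, while the additional
gain from B-mode conditioning did not materialize at this scale in our
experiments (the ablation matches the full model within seed noise).  The
likely reason is a joint property of scale and forward-model fidelity:
with 320 training phantoms and a clutter-free scatterer-summation model,
the normalized envelope features already expose the attenuation signal, so
the morphology-conditioned re-modulation has little left to correct.  The
acceptance protocol reports the measured improvement and its paired
t-test; treat the ablation *direction* at desk scale as an open
reproduction gap rather than a confirmed property.

## Clinical statistics

- **Grading** is threshold-inclusive: grade = number of cutoffs reached.
  PDFF cutoffs 5 / 16.3 / 21.6 % and QUS-AC cutoffs 0.36 / 0.46 / 0.53
  dB/cm/MHz for grades >=1 / >=2 / 3.
- **ICC** implements the two-way random-effects, absolute-agreement model
  from the ANOVA mean squares — ICC(2,1) for single ratings, ICC(2,k) for
  mean ratings — with F-based 95% confidence intervals (McGraw & Wong).
  Tests require exact agreement (1e-10) with an independent mean-squares
  decomposition and with `pingouin.intraclass_corr`.
- **ROC** uses the standard tie-corrected AUROC (equal to the pairwise
  concordance probability, verified exhaustively), a Youden-J operating
  point with score >= cutoff calling positive, contingency-table
  sensitivity/specificity/predictive values/likelihood ratios, and a
  2000-replicate stratified bootstrap CI.
- **Correlation/regression**: Spearman (tie-handling), Pearson, OLS with a
  slope CI; R^2 reported in percent.
- **Synthetic cohorts** come from a Gaussian copula with the study
  population's marginal means and SDs (PDFF 11.16 +/- 7.24 %, QUS-AC
  0.44 +/- 0.09 dB/cm/MHz, comparator modalities and demographics
  likewise), a configurable latent AC-PDFF correlation (default 0.9) and
  clipping to physical ranges.  The implied rank correlation is
  `6/pi asin(rho/2)`, which the generator reproduces within sampling
  error.  Patient-level published statistics (regressions, AUROC tables,
  ICC tables) depend on a private 35-patient dataset and are *not*
  reproduction targets; the machinery is validated on oracles and
  synthetic cohorts instead.

## Known limitations

- The forward model is single-scattering and refraction-free; artifacts
  that dominate difficult in-vivo imaging (aberration, reverberation
  unless enabled, off-plane clutter) are absent or first-order.
- Records whose liver is fully occluded by a sampled object are
  irreducibly ambiguous; they set a floor on desk-scale MNAE.
- The B-mode-conditioning benefit is not demonstrated at desk scale (see
  above); reproducing the reference 41% improvement likely requires the
  full 10,000-phantom, full-wave regime.
- 2-D phantoms and acquisitions only; no elastography, no 3-D.
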