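# Methods

## The model

A planar center-of-pressure (CoP) trajectory is treated as the superposition
of two latent fractional Brownian motion (fBm) components acting along
oblique axes:

    ml[i] = a1 eps1[i] cos(theta1) + a2 eps2[i] cos(theta2)
    ap[i] = a1 eps1[i] sin(theta1) + a2 eps2[i] sin(theta2)

where `eps_k` is an fBm path with Hurst exponent `H_k`, `theta_k` is an
*axial* direction (defined mod 180 degrees, measured from the mediolateral
platform axis) and `a_k` an amplitude on the increment scale.  The classical
decomposition along the anatomical AP/ML axes is the special case
`theta1 = 90, theta2 = 0`; the analysis exists to detect departures from it.
The standing assumptions are: components are independent, zero-mean
Gaussian, stationary in their increments, and the mixing is constant within
a trial.

## The per-trial analysis (oriented fractal scaling component analysis)

1. **Projection.** The trajectory is projected onto each direction of an
   axial grid, by default 179 angles `k*pi/179`, `k = 0..178` (180 degrees
   is the same axis as 0 and is excluded).
2. **Directional detrending moving average (DDMA).** For each window length
   `s` (odd), the centered moving least-squares polynomial of order `m`
   (a Savitzky-Golay trend; `m = 4` by default) is subtracted and the
   fluctuation `F(theta)(s)` is the RMS residual over indices covered by a
   full window.  The position series itself is the profile -- no extra
   cumulative sum -- so for an fBm projection the log-log slope of `F`
   against scale is the Hurst exponent directly.
3. **Scale conversion.** A window of `s` samples is sensitive to
   fluctuations at the shorter effective scale `s_eff = s / kappa(m)`.
   `kappa` is the characteristic frequency of the detrending residual
   filter: for a Brownian (`1/f^2`) input the spectral weight
   `S(f) |1 - H_SG(f)|^2` peaks at `f* = kappa(m)/s`, and `s_eff = 1/f*`.
   The frozen constants are `kappa(0) = 1.00`, `kappa(2) = 1.93`,
   `kappa(4) = 2.74` (see `scripts/calibrate_kappa.py`; the simulation-based
   estimator in `ofsca.ddma.estimate_kappa_from_fbm` recovers the same
   value from simulated fBm without using the analytic spectrum).
4. **Scaling profile.** Per angle, `H(theta)` is the least-squares slope of
   `log10 F` vs `log10 s_eff` restricted to the band `(1.5, 2.0)` in log10
   units -- about 0.3 s to 1 s at 100 Hz.  At least three scale points must
   fall inside the band.
5. **Extremal directions.** `theta_max` and `theta_min` are the circular
   argmax/argmin of `H(theta)` over the grid (exhaustive search; ties break
   toward the smaller angle; optional 3-point circular smoothing, off by
   default).  Because projecting orthogonally to a component annihilates
   it, the component axes are the 90-degree flips:
   `theta1 = theta_min + 90`, `theta2 = theta_max + 90` (mod 180), with
   `H1 = max H >= H2 = min H`.
6. **Summary scalars.** `delta_theta` is the axial difference between
   `theta1` and `theta2` folded into [0, 90] (90 = orthogonal, saddle-like
   organisation; smaller = suborthogonal).  `SD_H` is the population
   standard deviation of `H(theta)` over the full angle grid.
7. **Reconstruction.** Solving the 2x2 mixing system per sample at the
   fitted angles returns the component series; it is the exact inverse of
   the mixing when the true angles are supplied, and refuses near-collinear
   axes (condition number above 1e5).

A profile whose range `max H - min H` falls below 0.02 (configurable) is
flagged isotropic/degenerate: no directions are reported and the trial is
excluded from cohort tables with a logged count.

### Implementation note: the moments fast path

The trend operator is linear, so the residual of the projection at `theta`
is `cos(theta) r_ml + sin(theta) r_ap`, and `F^2(theta, s)` is a quadratic
form in the three residual second moments of the axes.  The default
`angular_fluctuation` computes each window's trend twice (once per axis)
instead of 179 times; the direct projection path is retained and the test
suite asserts the two are numerically identical.

## The cohort statistics stage

Per-trial summaries are assembled into a tidy table (one row per trial:
participant, vision in {EyesOpen, EyesClosed}, phase in {Before,
HeadRotation, After}, delta_theta, SD_H, H1, H2) and modelled with
random-intercept linear mixed models, treatment-coded against the
EyesOpen / Before baselines:

* model 1: `delta_theta ~ Vision + Phase + (1 | participant)`
* model 2: model 1 + `SD_H + H1 + H2`
* interaction variant: model 1 + `Vision:Phase` (kept only for the
  nested-model comparison; reported LRTs between nested models use ML
  refits, chi2 = 2 (ll_big - ll_small), df = parameter difference)

With a single random intercept the (RE)ML criterion profiles analytically
to one dimension in the variance ratio `tau^2/sigma^2`; the package
maximises the closed-form profile likelihood by bounded Brent search, which
is deterministic and cannot mis-converge in the way general-purpose mixed
solvers sometimes do on these tables.  Coefficient p-values use
Satterthwaite's approximation: for each coefficient,
`df = 2 g^2 / (grad g' A grad g)` where `g` is the coefficient's sampling
variance as a function of the variance parameters and `A` the inverse
negative Hessian of the REML log-likelihood (numerical derivatives).  The
test suite verifies estimates, standard errors, Satterthwaite df, p-values
and both log-likelihoods against R `lme4`/`lmerTest` on the same table.

## The synthetic cohort generator

No public recording accompanies the protocol the package emulates, so the
generator is a first-class module.  It mimics a balanced posturography
design: by default 17 participants x 6 conditions (2 vision x 3
head-rotation phases), one 20-s trial per cell at 100 Hz.  Per trial the
true axis separation is drawn from the linear mixed model itself:

    delta = base + intercept(participant) + effect(vision, phase) + noise(trial)

with `intercept ~ N(0, random_intercept_sd^2)` and
`noise ~ N(0, trial_noise_sd^2)`; `theta1` carries half-sized orientation
noise and `theta2 = theta1 - delta`.  Condition effects can also shift the
two Hurst exponents.

Defaults and where they come from:

| parameter | default | rationale |
|---|---|---|
| base components | H1 = 0.9 at 90 deg, H2 = 0.6 at 0 deg, amplitudes 1 | AP-dominant persistence of quiet stance |
| trial length / rate | 20 s at 100 Hz (n = 2000) | the emulated acquisition protocol |
| `trial_noise_sd` | 9.5 deg | back-solved from the published head-rotation SE (2.298) under the balanced design: SE = sigma sqrt(2/34) |
| `random_intercept_sd` | 6.5 deg | back-solved from the published intercept SE (2.290) after removing the residual share |
| head-rotation shift (tests) | -12.895 deg | the published fixed-effect size, used as a generator setting |
| baseline separation (statistics tests) | 81.2 deg | the published intercept; trajectory-level tests keep the orthogonal 90/0 geometry |

The drawn `delta` is deliberately **not** folded into [0, 90]: folding
would censor the Gaussian model the statistics stage is meant to recover
(with the defaults above, roughly a fifth of baseline draws would reflect
at 90 degrees, shrinking the between-participant variance and the injected
condition effect).  The generator therefore records the linear-model
response as ground truth and folds only when constructing the component
axes; the rare draw above 90 corresponds to axes whose realized axial
separation is the fold of the label.

fGn is synthesised by circulant embedding (Davies-Harte), which carries the
exact target autocovariance
`gamma(k) = (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}) / 2`; tests compare
sample autocovariances at lags 0-5 with the closed form at three standard
errors over 60 replicates.

### What the generator does not emulate

Real CoP data contain measurement noise, drift from postural resets,
nonstationary amplitude, hardware band-pass filtering and crossover scaling
regimes; the generator produces clean two-component mixtures with a single
scaling regime per component.  Passing recovery tests therefore demonstrate
the *method's* correctness under its own model, not robustness of the
decomposition on real recordings.

## Estimator behaviour the user should know

* **Single-trial angular noise.** At n = 2000 each scale's angular
  fluctuation carries only three degrees of freedom (the residual
  second-moment matrix), and the fitting band holds roughly 5-20
  effective independent windows per scale, so `H(theta)` has realization
  noise of order 0.1 and the extremum location wanders by over ten degrees
  from trial to trial.  This is intrinsic to the trial length, not a bug;
  seed-averaged directions are unbiased, which is what the recovery suite
  asserts (20 seeds per scenario).
* **Compression of extreme separations.** Because estimated `delta_theta`
  is folded into [0, 90], angular noise near orthogonality can only push
  estimates downward, so trial-level estimates of near-90-degree
  separations are biased slightly low and condition contrasts measured
  through the full pipeline are attenuated relative to the generator's
  truth.  The cohort-statistics acceptance checks therefore run on
  ground-truth tables (they test the modelling stage); the end-to-end
  pipeline is exercised separately for sign and significance.
* **Degenerate inputs.** Constant trajectories, flat profiles and
  near-collinear demixing raise or flag rather than returning numbers.

## Problem sizes

Calibration of `kappa` uses fBm paths of n = 2^16 for H in {0.3, 0.5, 0.7},
ten seeds each (the acceptance script's single reported quantity); scaling
consistency uses n = 2^14 over 20 seeds per H; recovery suites use the
protocol's n = 2000 over 20 seeds per scenario; the null-cohort type-I suite
uses 50 ground-truth cohorts of 102 trials.

## Known limitations

* Angle reporting is at grid resolution (pi/179); no sub-grid refinement of
  the extremum is attempted, and no confidence intervals on the fitted
  directions are provided.
* `kappa` is tabulated for detrending orders 0, 2 and 4 only.
* The statistics stage implements exactly one random-effects structure
  (participant intercepts), matching the target design; random slopes or
  crossed designs are out of scope.
* No multifractal (q-order) extension and no time-resolved (sliding-window)
  decomposition.
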