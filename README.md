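# ofsca

Oriented fractal scaling component analysis (OFSCA) of 2D center-of-pressure
trajectories, with a synthetic anisotropic sway generator and the
cohort-level mixed-effects stage, in Python.

## The problem

Postural sway recorded on a force platform is conventionally split along
the anatomical anteroposterior (AP) and mediolateral (ML) axes, implicitly
assuming the two control processes are orthogonal and aligned with the
hardware.  OFSCA drops that assumption: it models the 2D center-of-pressure
(CoP) trajectory as a superposition of **two oblique fractional Brownian
components** with distinct orientations `theta1, theta2` and Hurst
exponents `H1 > H2`, and estimates both axes from the data.  The angle
between the recovered axes, `delta_theta` (90 degrees = orthogonal,
"saddle-type" organisation; smaller = suborthogonal), then becomes the
response in mixed-effects comparisons across experimental conditions such
as vision and head rotation.

The method: project the trajectory onto 179 directions over the axial
half-circle; compute fourth-order detrending-moving-average fluctuation
functions `F(theta)(s_eff)` (effective scale `s_eff = s/2.74` for window
`s`); fit the angle-resolved scaling exponent `H(theta)` as the log-log
slope over `1.5 < log10 s_eff < 2.0` (about 0.3-1 s at 100 Hz); locate the
circular extrema of `H(theta)`; flip by 90 degrees to the component axes;
demix the trajectory along them.  `docs/methods.md` has the details and the
design decisions.

Who it is for: movement scientists who want the decomposition on their own
plain-CSV CoP recordings, and methodologists who want a tested, seedable
synthetic testbed for angle-resolved fractal analysis.

## Worked example

```python
from ofsca import ComponentSpec, analyze_trial, generate_trial

trial = generate_trial(
    ComponentSpec(hurst=0.9, angle_deg=90.0),   # persistent, AP-aligned
    ComponentSpec(hurst=0.6, angle_deg=30.0),   # weaker, 60 deg away
    seed=7,
)
res = analyze_trial(trial)
print(res.theta1_deg, res.theta2_deg, res.delta_theta_deg, res.h1, res.h2)
```

Running `python examples/02_decompose_trial.py` (the same computation with
commentary) prints:

```
H(theta) profile : max 0.834 at theta_max=117.7 deg, min 0.553 at theta_min=0.0 deg
component axes   : theta1_hat=90.0 deg (true 90), theta2_hat=27.7 deg (true 30)
axis separation  : delta_theta=62.3 deg (true 60)
profile spread   : SD_H=0.096
```

The profile's minimum at 0 degrees means projections along ML carry the
weakest temporal correlations, so the *strong* component must act 90
degrees away: `theta1_hat = 90`.  Likewise the maximum at 117.7 degrees
puts the weak component near 27.7 degrees.  The fitted exponents (0.83,
0.55) sit near the generating values (0.9, 0.6); single-trial angle
estimates carry realization noise of roughly ten degrees at this trial
length, and seed-averages are unbiased.

The other example scripts cover trial simulation
(`01_simulate_sway_trial.py`), the window-to-scale calibration
(`03_kappa_calibration.py`) and the cohort mixed-model stage
(`04_cohort_statistics.py`).

## Command line

A thin CLI wraps the library for shell pipelines:

```
ofsca simulate --participants 17 --seed 1 --out cohort/
ofsca analyze cohort/trial_P01_EyesOpen_Before.csv
ofsca run cohort/manifest.csv --out results/
ofsca cohort results/cohort.csv --model 1 --lrt
```

Trajectories are plain CSV (`time_s,ml,ap`), cohorts a manifest CSV plus a
ground-truth JSON sidecar, results JSON.

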