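"""Decompose a single trial: angle-resolved scaling and component directions.

Runs the full per-trial pipeline on a synthetic trial whose component axes
are 60 degrees apart, then prints the fitted directions and exponents next
to the ground truth.
"""

import numpy as np

from ofsca import ComponentSpec, analyze_trial, generate_trial

true = dict(theta1=90.0, h1=0.9, theta2=30.0, h2=0.6)  # 60 deg apart
trial = generate_trial(
    ComponentSpec(true["h1"], true["theta1"]),
    ComponentSpec(true["h2"], true["theta2"]),
    seed=7,
)
res = analyze_trial(trial)

print(f"H(theta) profile : max {res.h1:.3f} at theta_max={res.theta_max_deg:.1f} deg, "
      f"min {res.h2:.3f} at theta_min={res.theta_min_deg:.1f} deg")
print(f"component axes   : theta1_hat={res.theta1_deg:.1f} deg (true {true['theta1']:.0f}), "
      f"theta2_hat={res.theta2_deg:.1f} deg (true {true['theta2']:.0f})")
print(f"axis separation  : delta_theta={res.delta_theta_deg:.1f} deg (true 60)")
print(f"profile spread   : SD_H={res.sd_h:.3f}")
print(f"reconstructed component sds: {np.std(res.eps1_hat):.2f}, {np.std(res.eps2_hat):.2f}")
print()
print("theta1/theta2 are the axes along which the two fractal components act;")
print("they sit 90 deg away from the extrema of the angle-resolved scaling")
print("exponent H(theta), because projecting orthogonally to a component")
print("removes it.  Single-trial angle estimates carry ~10-15 deg of")
print("realization noise at this trial length; seed-averages are unbiased.")
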