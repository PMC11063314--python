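"""Cohort-level mixed models: does head rotation narrow the axis separation?

Simulates the ground truth of a 17-participant x 6-condition cohort in which
head rotation shifts the angle between component axes by -12.895 degrees,
then fits the random-intercept mixed model of delta-theta on Vision and
Phase and reports the recovered coefficients.
"""

from ofsca import (
    CohortDesign,
    ComponentSpec,
    ConditionEffect,
    fit_interaction_model,
    fit_model1,
    generate_cohort_truth,
    likelihood_ratio_test,
)

effect = ConditionEffect(delta_theta_deg=-12.895)
design = CohortDesign(
    effect_map={
        ("EyesOpen", "HeadRotation"): effect,
        ("EyesClosed", "HeadRotation"): effect,
    },
    base_spec1=ComponentSpec(0.9, 90.0),
    base_spec2=ComponentSpec(0.6, 8.8),  # baseline separation 81.2 deg
)
table = generate_cohort_truth(design, seed=1)
fit = fit_model1(table)

print(f"{len(table)} trials, {fit.n_groups} participants")
print(fit.terms.round(3).to_string())
print(f"\nresidual sd {fit.residual_var ** 0.5:.2f} deg, "
      f"participant-intercept sd {fit.intercept_var ** 0.5:.2f} deg")

lrt = likelihood_ratio_test(fit, fit_interaction_model(table))
print(f"Vision x Phase interaction LRT: chi2({lrt.df}) = {lrt.chi2:.3f}, p = {lrt.p:.3f}")
print()
print("The Phase[HeadRotation] coefficient estimates how much the angle")
print("between the two postural control axes narrows while the head turns;")
print("it should sit within ~2 SE of the injected -12.895 deg.  The")
print("interaction adds nothing here, matching its null role in the design.")
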