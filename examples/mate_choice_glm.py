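"""Fit the weighted binomial GLM to synthetic UV-manipulation choice trials.

Males choose between a conspecific and a comimic female model under two
treatments (UV reflectance intact vs blocked). The generator plants a
known preference shift (comimic approached more once UV is removed) and
the GLM recovers it: the response is the per-male proportion of events
toward the comimic, weighted by the per-male event total.
"""

import numpy as np

import mimicvis as mv

rng = np.random.default_rng(0)
trials, truth = mv.reference_scale_trials(rng)
table = mv.build_choice_table(trials, behavior="approach")
fit = mv.fit_weighted_binomial(table, design="treatment")

print(f"Males: {table['male_id'].nunique()}, total approach events: "
      f"{int(table['weight'].sum())}")
print("\nCoefficients (logit scale):")
print(fit.coefficient_table().to_string(index=False,
                                        float_format=lambda v: f"{v: .4f}"))
z, p = mv.wald_test(fit, "treatment[UVminus]")
true_shift = truth["log_odds_approach"]["UVminus"] \
    - truth["log_odds_approach"]["UVplus"]
print(f"\nTrue planted treatment shift: {true_shift:.3f} log odds")
print(f"Wald test of the UV-blocked effect: z = {z:.3f}, p = {p:.3g}")
print("\nA positive treatment coefficient means males direct more of their "
      "approaches at the comimic when UV cues are removed - UV reflectance "
      "helps them find the right species.")
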