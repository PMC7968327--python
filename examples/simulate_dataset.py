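"""Draw a synthetic two-occasion SF-36 dataset from the generating model.

The default generator embodies the fitted final model of the hypertension
disease-management cohort: two latent factors (general physical and mental
health) at baseline and 4-week follow-up, with a uniform recalibration of
SF, non-uniform recalibration of RP and BP, and true change in both
factor means.  `inject_rs` can plant additional response-shift effects.
"""

import rshift as rs

params = rs.default_generating_model()
data = rs.simulate(params, n=203, seed=42)

print(data.head().round(1))
print(f"\n{len(data)} respondents x {data.shape[1]} columns "
      "(8 scales x 2 occasions)")

# the SF follow-up mean combines the recalibrated intercept (87.29) with
# the deteriorated mental-health factor (-0.165 x loading 12.508):
implied = 87.290 + 12.508 * (-0.165)
print(f"\nSF_t2: sample mean {data['SF_t2'].mean():.2f}, "
      f"population value {implied:.2f}")

# planting an extra effect: reprioritization of PF (its loading grows at t2)
shifted = rs.inject_rs(params, "PF", "reprioritization", 5.0)
print("\nPF loading at t2 after injection:",
      shifted.lambda_t2[0, 0], "(was", params.lambda_t2[0, 0], ")")
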