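"""Run the full 4-step response-shift detection procedure.

Simulates a large cohort from the default generator (which contains a
uniform recalibration of SF and non-uniform recalibration of RP and BP)
and runs the pipeline: measurement-model gate, overall response-shift
test, modification-index-guided backward release at alpha = 0.05/8, and
factor-level invariance tests yielding the adjusted change.
"""

import rshift as rs

data = rs.simulate(rs.default_generating_model(), n=2000, seed=31)
report = rs.run(data, {"estimator": "ML"})

print(rs.report_markdown(report))

print("Interpretation: the three detected effects are the planted ones —")
print("respondents rated SF higher at follow-up for a given mental-health")
print("level (uniform recalibration), and the RP/BP residual variances")
print("changed (non-uniform recalibration, zero mean effect).  After")
print("removing them, physical health improved and mental health declined.")
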