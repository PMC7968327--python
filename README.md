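# rshift — response-shift detection in two-occasion HRQOL data

When people repeatedly self-report their health-related quality of life
(HRQOL), the meaning of their answers can drift: internal standards
recalibrate, values reprioritize, the construct itself gets
reconceptualized.  This *response shift* (RS) confounds observed change —
a patient may score their social functioning higher at follow-up not
because it improved but because a disease-management program changed what
"good" means to them.  `rshift` implements the 4-step structural-equation-
modeling procedure (Oort's approach) that separates response shift from
true change in two-occasion SF-36 scale scores, for biostatisticians and
outcomes researchers analyzing longitudinal patient-reported data.

## The model

Eight scale scores $y$ (PF, RP, BP, RE, GH, SF, VT, MH; each 0–100) at
baseline and follow-up measure two common factors per occasion — general
physical health (GenPHYS: PF, RP, BP, RE) and general mental health
(GenMENT: GH, SF, VT, MH):

$$y_t = \tau_t + \Lambda_t \eta_t + \varepsilon_t, \qquad
\Sigma = \Lambda \Phi \Lambda' + \Theta, \quad \mu = \tau + \Lambda\kappa$$

with residuals correlated across occasions (and RP with RE within
occasions).  Occasion-1 factor means and variances are fixed at 0 and 1.
The procedure:

1. **Measurement model** (Model 1, df 88): all RS-related parameters
   ($\Lambda, \tau, \operatorname{diag}\Theta$) free per occasion; the fit
   gate CFI, TLI > 0.9, SRMR < 0.1, RMSEA < 0.08 must pass.
2. **No-RS model** (Model 2, df 108): those parameters constrained equal
   across occasions; the 20-df (Satorra–Bentler scaled) $\chi^2$
   difference test detects response shift overall.
3. **Backward release** (Model 3): the largest-modification-index
   constraint is released and kept if its 1-df difference test beats the
   Bonferroni-adjusted $\alpha = 0.05/8$.  Released intercepts are uniform
   recalibration, residual variances non-uniform recalibration, loadings
   reprioritization, pattern additions reconceptualization.
4. **Adjusted change** (Model 4): factor correlations, variances and means
   are tested for invariance; the across-occasion factor-mean differences
   in the final model are the RS-adjusted ("true") change, and effect
   sizes decompose each scale's observed standardized change into an RS
   component plus adjusted change.

Estimation is normal-theory ML on means and covariances
($T = (n-1)F_{\mathrm{ML}}$), with an optional robust (MLR-style)
chi-square scaling factor $c = \operatorname{tr}(U\Gamma)/df$ estimated
from fourth moments, and Satorra–Bentler scaled difference tests.  No
patient data are distributed; a synthetic-data generator parameterized by
the published final-model solution makes the whole pipeline testable.

## Worked example

Recover the published estimates from the generator's population moments
(`python examples/population_recovery.py`):

```
df = 106, discrepancy T = 4.01e-25 (0 means exact fit)

parameter                                      recovered generating
SF intercept, t2 (uniform recalibration)         87.2900     87.290
RP residual variance, t2                        492.0100    492.010
BP residual variance, t2                        125.9400    125.940
GenPHYS mean, t2 (adjusted change)                0.2340      0.234
GenMENT mean, t2 (adjusted change)               -0.1650     -0.165
GenPHYS variance, t2                              1.1360      1.136
GenMENT variance, t2                              0.7810      0.781
```

The discrepancy of ~0 says the final-model specification fits the
generator's population moments exactly, and every response-shift and
change parameter returns to its generating value — the estimation engine
and the constraint algebra are mutually consistent.

Run the full detection on a simulated cohort
(`python examples/detect_response_shift.py`, n = 2000):

```
| Scale | Type                      | chisq(1) | p         | order |
| RP    | non-uniform recalibration | 502.43   | 2.81e-111 | 1     |
| BP    | non-uniform recalibration | 200.93   | 1.31e-45  | 2     |
| SF    | uniform recalibration     | 180.91   | 3.07e-41  | 3     |

| Factor  | change | p        | effect size | label      |
| GenPHYS | +0.243 | 5.8e-45  | +0.24       | small      |
| GenMENT | -0.183 | 1.9e-12  | -0.18       | negligible |
```

The three detected effects are exactly the ones embodied in the
generator; after removing them, physical health improved and mental
health declined — the adjusted change.  For SF the decomposition reads
observed +0.25 = RS +0.37 + adjusted −0.12: recalibration masks a real
deterioration as an apparent improvement.

A thin CLI wraps the same operations:

```sh
rshift simulate --n 203 --seed 42 --out sim.csv
rshift detect --data sim.csv --out report.json --markdown report.md
```

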