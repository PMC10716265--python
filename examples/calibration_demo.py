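"""Isotonic calibration of raw risk scores into event probabilities.

Raw model scores are monotonically related to risk but are not
probabilities. Pool-adjacent-violators regression on a natural-prevalence
calibration cohort maps them onto the probability of observing AF in the
monitoring window; the fitted map preserves the cohort prevalence exactly
and never reorders subjects.
"""

import numpy as np

from afhorizon import fit_calibration

rng = np.random.default_rng(0)

# calibration cohort: raw scores in (0, 1), true risk = score^2
s_cal = rng.random(3000)
y_cal = (rng.random(3000) < s_cal ** 2).astype(float)
cal = fit_calibration(s_cal, y_cal, age_group="65-74")

print(f"calibration cohort prevalence: {y_cal.mean():.3f}")
print(f"mean calibrated probability:   {cal(s_cal).mean():.3f} "
      "(equal by construction)")
print(f"PAVA blocks: {cal.breakpoints.size}")

# held-out reliability by decile of calibrated probability
s_test = rng.random(3000)
y_test = (rng.random(3000) < s_test ** 2).astype(float)
p = cal(s_test)
edges = np.quantile(p, np.linspace(0, 1, 11))
print("decile  predicted  observed")
for i in range(10):
    m = (p >= edges[i]) & (p <= edges[i + 1])
    print(f"  {i + 1:2d}     {p[m].mean():.3f}     {y_test[m].mean():.3f}")
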