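"""Discrimination metrics with bootstrap uncertainty and model comparison.

AUC is the probability a random AF-positive recording outscores a random
negative one; average precision summarises the precision-recall curve and
tracks prevalence. The percentile bootstrap gives confidence intervals;
the paired bootstrap compares two models on identical resamples.
"""

import numpy as np

from afhorizon import (average_precision, bootstrap_ci,
                       operating_point_at_sensitivity,
                       paired_bootstrap_test, roc_auc)

rng = np.random.default_rng(1)
n = 400
labels = (rng.random(n) < 0.15).astype(float)          # 15% prevalence
informed = labels + 0.6 * rng.standard_normal(n)       # a useful model
guessing = rng.random(n)                               # an uninformative one

auc_ci = bootstrap_ci(roc_auc, informed, labels, n_boot=2000, seed=0)
print(f"informed model AUC {auc_ci.point:.3f} "
      f"(95% CI {auc_ci.low:.3f}-{auc_ci.high:.3f})")
print(f"average precision {average_precision(informed, labels):.3f} "
      f"(prevalence {labels.mean():.3f})")

op = operating_point_at_sensitivity(informed, labels, target_sens=0.80)
print(f"at sensitivity {op.sensitivity:.2f}: specificity {op.specificity:.2f}, "
      f"precision {op.precision:.2f}, F1 {op.f1:.2f}")

cmp = paired_bootstrap_test(roc_auc, informed, guessing, labels,
                            n_boot=2000, seed=0)
print(f"informed vs guessing: delta AUC {cmp.delta:+.3f} "
      f"(95% CI {cmp.low:+.3f} to {cmp.high:+.3f}), "
      f"two-sided p = {cmp.p_value:.4f}")
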