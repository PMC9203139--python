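"""The precision-recall no-skill baseline on an imbalanced cohort.

Under the average-precision convention, a classifier with uninformative
(constant) scores attains a PR area exactly equal to the event prevalence —
the natural chance line when 25 of 60 patients die. ROC AUC of the same
classifier is 0.5 regardless of prevalence, which is why PR area is the
preferred objective here.
"""

import numpy as np

from metaborank import pr_auc, roc_auc

labels = np.array([1] * 25 + [0] * 35)  # 25 events in 60 patients
constant = np.full(60, 0.5)

print(f"event rate:               {labels.mean():.4f}")
print(f"constant-classifier PR-AUC: {pr_auc(constant, labels):.4f}")
print(f"constant-classifier ROC-AUC: {roc_auc(constant, labels):.4f}")

rng = np.random.default_rng(0)
informative = labels + rng.normal(scale=0.8, size=60)
print(f"\nan informative score:     PR-AUC {pr_auc(informative, labels):.3f}, "
      f"ROC-AUC {roc_auc(informative, labels):.3f}")
# Any model worth keeping must beat the 0.4167 PR baseline, not 0.5.
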