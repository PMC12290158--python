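"""Generate the synthetic biased dataset and resample it by group rate.

Draws 2000 class-balanced rows from the two class-conditional Gaussians,
derives the protected attribute from the sign of the first feature, and
builds nested training subsets at target unprivileged group rates.
"""

import numpy as np

from fairpost import SyntheticConfig, plan_ugr, resample_to_ugr, simulate_dataset

ds = simulate_dataset(SyntheticConfig(s=0.0, n_per_class=1000, seed=42))
unpriv = ds.protected["A"] == 0
print(f"dataset: {ds.n} rows, {int(ds.labels.sum())} favorable")
print(f"unprivileged share of favorable class:   {np.mean(unpriv[ds.labels == 1]):.3f}")
print(f"unprivileged share of unfavorable class: {np.mean(unpriv[ds.labels == 0]):.3f}")
# The protected attribute is coupled to the class structure: under s=0 the
# unprivileged group holds ~18% of favorable but ~73% of unfavorable cases.

targets = [0.1, 0.3, 0.5, 0.7, 0.9]
plans = [plan_ugr(ds, r) for r in targets]
subsets = resample_to_ugr(ds, plans, seed=0)
print("\ntarget UGR  subset size  achieved UGR  favorable share")
for plan, sub in zip(plans, subsets):
    achieved = np.mean(sub.protected["A"] == 0)
    print(f"   {plan.target_ugr:.1f}        {sub.n:5d}        {achieved:.3f}"
          f"         {sub.labels.mean():.2f}")
# Each subset is exactly class balanced; its size is the largest the four
# (group, class) supplies allow, and rows are nested cell-wise across targets.
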