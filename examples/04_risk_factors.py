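"""Risk factors for early recurrence: screen, multivariable model, ROC.

Univariable logistic fits screen eleven candidate factors at p < 0.10;
survivors enter a joint model whose odds ratios carry Wald 95% intervals.
"""

import numpy as np

from pnetrecur import SyntheticConfig, generate_cohort, roc_auc
from pnetrecur.logistic import build_outcome, multivariable_model, univariable_screen

records, _ = generate_cohort(SyntheticConfig(seed=7))

screen = univariable_screen(records, outcome_tag="early", cutoff_months=18)
print("univariable screen (early recurrence vs all other patients):")
print(
    screen.table[["odds_ratio", "ci_low", "ci_high", "p", "included"]].to_string(
        float_format=lambda v: f"{v:.3g}"
    )
)

fit = multivariable_model(records, screen.included, outcome_tag="early")
print(f"\nmultivariable model (n={fit.n}, converged in {fit.n_iter} iterations):")
print(
    fit.table[["odds_ratio", "ci_low", "ci_high", "p"]].to_string(
        float_format=lambda v: f"{v:.3g}"
    )
)

y = build_outcome(records, "early", 18.0).astype(bool)
sizes = np.array([r.tumor_size for r in records])
print(f"\ntumor size AUC for early recurrence: {roc_auc(sizes, y).auc:.3f}")

# Tumor size (per cm) and nodal positivity should dominate: they are the
# factors the generator wires into early-class membership.  An AUC near
# 0.65-0.75 means size alone is a useful but imperfect discriminator.
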