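"""Discrimination and internal validation of the IDS.

ROC with DeLong CI and Youden operating point for patients vs controls,
then Harrell bootstrap optimism correction and repeated 10-fold CV of the
four-feature composite model.
"""

import numpy as np

from immunebalance import (
    SimulationConfig,
    bootstrap_optimism,
    compute_score_table,
    generate_cohort,
    logistic_spec,
    repeated_cv,
    roc_auc,
)

cohort = generate_cohort(SimulationConfig(seed=7).scale_effects(2.0))
t = compute_score_table(cohort).table
y = (t["group"] == "patient").astype(int).to_numpy()

roc = roc_auc(t["ids"].to_numpy(), y)
print(f"IDS AUC = {roc.auc:.3f} (95% CI {roc.ci_low:.3f}-{roc.ci_high:.3f})")
print(f"Youden threshold {roc.youden_threshold:.3f}: "
      f"sens {roc.youden_sensitivity:.1%}, spec {roc.youden_specificity:.1%}")

X = t[["pro_mean", "anti_mean", "ids", "delta_ids"]].to_numpy()
rep = bootstrap_optimism(logistic_spec, X, y, metric="auc", B=500, seed=0)
print(f"composite model: apparent AUC {rep.apparent:.3f}, "
      f"optimism {rep.optimism:.3f}, corrected {rep.corrected:.3f}")

cv = repeated_cv(logistic_spec, X, y, k=10, repeats=5, metric="auc", seed=0)
print(f"repeated 10-fold CV AUC: {cv['mean']:.3f} +/- {cv['sd']:.3f}")
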