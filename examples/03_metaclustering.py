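"""SOM metaclustering of sample immunophenotypes.

Trains a 4x4 self-organizing map on the cohort's subset-frequency vectors,
merges nodes into 8 metaclusters, and prints the per-group composition with
bootstrap confidence intervals on the patient-control differences.
"""

from immunebalance import (
    SimulationConfig,
    assign_and_compose,
    composition_differences,
    compute_score_table,
    generate_cohort,
    metacluster,
    metacluster_ids_weights,
    train_som,
)

cohort = generate_cohort(SimulationConfig(seed=7).scale_effects(2.0))
som = train_som(cohort.subset_matrix, grid=(4, 4), epochs=200, seed=1)
assignment = assign_and_compose(cohort, som, metacluster(som, k=8))

print("composition (fraction of samples per metacluster):")
print(assignment.composition.round(3).to_string())

diffs = composition_differences(assignment, cohort.group_labels, n_boot=1000, seed=2)
print("\npatient - control differences (percentage points, 95% CI):")
print(diffs[["difference_pp", "ci_low", "ci_high"]].round(1).to_string())

ids_vals = compute_score_table(cohort)["ids"]
print("\nmetacluster IDS weights (membership-score correlation):")
print(metacluster_ids_weights(assignment, ids_vals).round(3).to_string())
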