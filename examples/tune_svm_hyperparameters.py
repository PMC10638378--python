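"""Tune an RBF-SVM's (C, gamma) with TSDPSO on a synthetic cohort.

Generates a moderately separated synthetic clinical cohort, then lets a
small swarm search the (log2 C, log2 gamma) box for the parameters
minimizing 5-fold cross-validated misclassification.
"""

from tsdpso import CohortSpec, CVSpec, SwarmConfig, generate_cohort, tune_svm_tsdpso

cohort = generate_cohort(CohortSpec(n_per_class=150, delta=1.5, seed=0))
y = cohort["FRI"].to_numpy()
x = cohort.drop(columns=["FRI"]).to_numpy(float)

best, trace, model = tune_svm_tsdpso(
    x,
    y,
    swarm_config=SwarmConfig(swarm_size=8, max_iterations=10, seed=0),
    cv=CVSpec(folds=5, seed=0),
)

print(f"best C      : {best.C:.4g}")
print(f"best gamma  : {best.gamma:.4g}")
print(f"CV error    : {trace.gbest_fitness:.4f}")
print("CV error is the mean held-out misclassification rate at the tuned")
print("parameters; the swarm searched in log2 space inside C in [2^-5, 2^15],")
print("gamma in [2^-15, 2^3].")
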