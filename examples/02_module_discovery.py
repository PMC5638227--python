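"""Full module discovery on a simulated cohort.

Generates a 30-gene, 200-sample cohort with two planted 3-gene modules that
co-occur internally and are mutually exclusive with each other, then runs
the complete BeME-WithCo pipeline: pair tests, network construction,
between/within weights, and the exact ILP solve.
"""

from bewith import BeWithConfig, generate_instance, recovery_score, run_planted_pipeline

matrix, edges, truth = generate_instance(seed=7, epsilon=0.01)
print(f"cohort: {matrix.n_genes} genes x {matrix.n_samples} samples")
print(f"planted modules: {truth.planted_modules}")

config = BeWithConfig(k_modules=2, max_module_size=3)
assignment = run_planted_pipeline(matrix, edges, "beme-withco", config,
                                  alpha_me=0.05, alpha_co=0.05, seed=8)

print(f"\nobjective: {assignment.objective:.3f}")
for k, module in enumerate(assignment.nonempty_modules(), start=1):
    print(f"module {k}: {module}")
score = recovery_score(truth, assignment)
print(f"exact recovery: {score['exact']}, mean best Jaccard: {score['best_jaccard']:.2f}")
print()
print("The objective sums co-occurrence weight inside modules and mutual-")
print("exclusivity weight across them; exact recovery 1 means the solver")
print("returned precisely the planted gene sets.")
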