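"""Frequency-weighted pair tests on a tiny cohort.

Builds an 8-sample matrix in which genes A and B are mutated in disjoint
sample sets (a classic exclusivity pattern) while C co-occurs with A, then
runs the weighted-sampling exclusivity (WeSME) and co-occurrence (WeSCO)
tests plus the closed-form hypergeometric co-occurrence test.
"""

import numpy as np

from bewith import MutationMatrix, hypergeom_cooccurrence, wesco_pvalue, wesme_pvalue

values = np.array([
    # s1 s2 s3 s4 s5 s6 s7 s8
    [1, 1, 1, 1, 0, 0, 0, 0],   # A
    [0, 0, 0, 0, 1, 1, 1, 1],   # B: never with A
    [1, 1, 1, 0, 0, 0, 0, 0],   # C: always with A
])
m = MutationMatrix(genes=["A", "B", "C"], samples=[f"s{i}" for i in range(1, 9)],
                   values=values)

me = wesme_pvalue(m, "A", "B", n_draws=20000, seed=1)
co = wesco_pvalue(m, "A", "C", n_draws=20000, seed=1)
hyper = hypergeom_cooccurrence(3, 4, 3, 8)

print(f"A vs B exclusivity (WeSME):    p = {me.p_value:.4f}  (coverage {me.coverage}/8)")
print(f"A vs C co-occurrence (WeSCO):  p = {co.p_value:.4f}  (overlap {co.overlap})")
print(f"A vs C co-occurrence (hypergeometric): p = {hyper:.4f}")
print()
print("Small p-values mean the observed pattern is unlikely under a null that")
print("replaces each gene's mutated samples at random, weighted by how heavily")
print("mutated each sample is overall.")
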