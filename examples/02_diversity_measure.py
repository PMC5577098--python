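"""The disagreement diversity measure on classifier correctness vectors.

Two classifiers are 'diverse' when they err on different samples: the
measure is the fraction of samples on which exactly one of the two is
correct (normalised Hamming distance between their 0/1 correctness
vectors). Overall diversity OD[i] aggregates learner i's row of the
pairwise matrix.
"""

import pathvote as pv

# correctness over 4 labelled samples (1 = classified correctly)
y_a = [1, 1, 0, 0]
y_b = [1, 0, 1, 0]
y_c = [0, 0, 1, 1]

print("pairwise disagreement:")
print(f"  D(a,b) = {pv.disagreement(y_a, y_b)}   (they differ on 2 of 4 samples)")
print(f"  D(a,c) = {pv.disagreement(y_a, y_c)}   (complementary -> maximal diversity)")
print(f"  D(a,a) = {pv.disagreement(y_a, y_a)}   (identical -> no diversity)")

D = pv.diversity_matrix([[y_a, y_b, y_c]], learner_ids=["a", "b", "c"])
print("\ndiversity matrix (symmetric, zero diagonal):")
print(D.matrix)

od = pv.overall_diversity(D)
print("\noverall diversity OD[i] = sum_j (D[i,j] + D[j,i]):")
for lid, v in zip(D.learner_ids, od):
    print(f"  OD[{lid}] = {v}")
print("'a' and 'c' tie for the highest OD (they are mutually complementary),")
print("so the optimiser would try them first when growing the ensemble.")
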