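"""Classify duplicated gene pairs into AED / Sub / NoDiff.

Simulates replicated negative-binomial expression for pairs with planted
divergence categories, runs the per-sample Welch tests with BH correction,
applies the classification rules, and compares against the planted truth.
"""

import pandas as pd

import t2tdup as T
from t2tdup.expression import category_counts

cats = ["AED", "Sub", "NoDiff"]
pairs = pd.DataFrame(
    [{"pair_id": f"P{i:02d}", "gene_a": f"a{i}", "gene_b": f"b{i}",
      "category": cats[i % 3]} for i in range(18)])

design = T.ExpressionDesign()  # 11 samples x 3 replicates
counts, tpm, truth = T.simulate_expression(pairs, design, seed=0)
planted = {k: int(v) for k, v in pairs["category"].value_counts().items()}
print(f"simulated {tpm.shape[0]} genes x {tpm.shape[1]} columns "
      f"({design.n_samples} samples x {design.n_replicates} replicates); "
      f"planted categories: {planted}")

called, statuses = T.classify_pairs(pairs, tpm)
print(f"called categories: {category_counts(called)}")
agree = sum(p == c.category for p, c in zip(pairs["category"], called))
print(f"agreement with planted truth: {agree}/{len(pairs)}")

corr, _ = T.pair_correlations(
    {"duplicates": list(zip(pairs["gene_a"], pairs["gene_b"])),
     "random": T.random_pairs(list(tpm.index), n=50, seed=1)}, tpm)
print(corr.groupby("group")["r"].agg(["mean", "count"]).round(3))
print()
print("Duplicate pairs share a sample profile, so their expression "
      "correlation sits far above the random-pair baseline near zero — "
      "the signature used to argue duplicates retain coupled regulation.")
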