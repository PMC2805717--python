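"""Simulate a reference panel and an admixed study cohort with planted eQTLs.

Builds the default study: a two-population Balding-Nichols reference panel
(F_ST = 0.2), a 60-sample cohort with Dirichlet(1,1) admixture, and 100
expression traits of which 30 carry a cis effect sized near r^2 = 0.5.
"""

import numpy as np

from admixqtl import SimulationConfig, generate_study

cfg = SimulationConfig(seed=1)
cohort, expr, truth = generate_study(cfg)

print(f"reference panel: {cohort.reference.n_samples} samples x "
      f"{cohort.reference.n_snps} SNPs, populations "
      f"{sorted(set(cohort.reference.pop_labels))}")
print(f"study cohort:    {cohort.genotypes.n_samples} samples x "
      f"{cohort.genotypes.n_snps} SNPs")
print(f"mean ancestry-1 proportion: {cohort.true_Q[:, 0].mean():.3f} "
      "(Dirichlet(1,1) -> about 0.5)")
print(f"expression: {expr.n_traits} traits, "
      f"{truth.table['causal_snp_id'].notna().sum()} with a planted cis eQTL")

# the planted effect explains about half the trait variance by construction
causal = truth.table.dropna(subset=["causal_snp_id"]).iloc[0]
j = cohort.genotypes.snp_ids.index(causal["causal_snp_id"])
g = cohort.genotypes.dosage[:, j]
y = expr.values[:, 0]
r = np.corrcoef(g, y)[0, 1]
print(f"first cis trait vs its causal SNP: correlation {r:.2f} "
      f"(r^2 {r**2:.2f})")
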