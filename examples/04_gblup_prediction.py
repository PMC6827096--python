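"""Simulate a trait and predict breeding values with GBLUP.

A single simulated breed is split into reference (phenotyped) and
validation (held out) sets; the Yang-estimator GRM carries relationship
information from reference to validation, and prediction accuracy is the
correlation between predicted and true breeding values.
"""

import numpy as np

import mbgp

config = mbgp.FounderConfig(
    founders_per_breed={"B1": 25},
    group_assignment={"B1": "g"},
    n_markers=4000,
    n_chromosomes=2,
    seed=11,
)
founders = mbgp.generate_founders(config)
panel = mbgp.expand_breed(
    founders, "B1", mbgp.ResampleConfig(500, 1000, seed=12)
)

h2 = 0.5
qtl = mbgp.sample_qtl(panel, "I", seed=13)  # 100 large-effect QTL
tbv = mbgp.compute_tbv(panel, qtl)
trait = mbgp.simulate_phenotypes(tbv, h2, seed=14)
print(f"simulated {qtl.n_qtl} QTL; realized heritability "
      f"{trait.realized_h2:.3f} (target {h2})")

grm = mbgp.compute_grm(panel)
print(f"GRM over {grm.n} individuals from {grm.n_markers} markers; "
      f"mean diagonal {np.mean(np.diag(grm.matrix)):.3f}")

ref = np.arange(800)
val = np.arange(800, 1000)
lam = (1 - h2) / h2
b_hat, gebv = mbgp.fit_gblup(trait.phenotype[ref], None, grm, ref, lam, val)
acc = mbgp.accuracy(gebv[val], tbv[val])
print(f"fixed-effect mean estimate: {b_hat[0]:.3f}")
print(f"validation accuracy cor(GEBV, TBV) = {acc:.3f} for 200 held-out "
      f"individuals predicted from 800 phenotyped relatives")

sg2, se2 = mbgp.estimate_variances_reml(
    trait.phenotype[ref], None,
    grm.matrix[np.ix_(ref, ref)],
)
print(f"EM-REML variance components: h2_hat = {sg2 / (sg2 + se2):.3f}")
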