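"""Kinship-aware logistic association of a latent score with a diagnosis.

Simulates a family cohort with a binary outcome at ~16% prevalence whose
log-odds increase by log(1.39) per latent-trait unit plus a
kinship-structured random effect, fits the penalized quasi-likelihood
logistic mixed model, and prints the odds ratio with the eigenvalue-based
multiple-testing threshold.
"""

import numpy as np

import twinscales as ts
from twinscales.pedigree import relatedness_block_fn

cfg = ts.make_config(n_mz_pairs=300, n_dz_pairs=450, p_extra_sib=0.13,
                     n_singletons=300, seed=40)
_, pedigree, truth = ts.simulate_cohort(cfg)
K = ts.relatedness_matrix(pedigree).to_numpy()
dx = ts.simulate_diagnoses(truth, K,
                           ts.DiagnosisParams(slope=float(np.log(1.39)),
                                              polygenic_var=0.3), seed=41)

df = pedigree.merge(truth.theta, on="person_id").merge(dx, on="person_id")
X = np.column_stack([np.ones(len(df)), df["trait_0"],
                     (df["sex"] == "F").astype(float),
                     df["age"] - df["age"].mean(),
                     df["age_at_interview"] - df["age_at_interview"].mean()])
res = ts.pql_logistic_mixed(df["dx_0"].to_numpy(float), X,
                            df["family_id"].to_numpy(),
                            relatedness_block_fn(df, pedigree))

print(f"n = {res.n}, outcome prevalence = {df['dx_0'].mean():.2f}")
print(f"odds ratio per latent unit: {res.odds_ratio:.2f} "
      f"[{res.or_ci[0]:.2f}, {res.or_ci[1]:.2f}], p = {res.p:.2e}")
print(f"kinship variance component: {res.sg2:.2f}")

# multiplicity: 8 correlated scores, 4 outcomes
rng = np.random.default_rng(42)
base = rng.standard_normal((500, 1))
scores = base + 0.8 * rng.standard_normal((500, 8))
n_eff = ts.effective_tests(scores)
thr = ts.bonferroni_threshold(n_eff, 4)
print(f"effective number of independent scores: {n_eff:.1f} "
      f"-> corrected threshold {thr:.1E}")
print()
print("The odds ratio should recover ~1.39; modelling the familial "
      "covariance keeps the test honest in related samples, and the "
      "eigenvalue estimator softens Bonferroni for correlated scores.")
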