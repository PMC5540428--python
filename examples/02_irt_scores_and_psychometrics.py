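"""Latent IRT scores and classical psychometrics for the packaged scales.

Simulates a default twin cohort, fits kernel item curves for the 14-item
anxiety-depression scale, computes ML latent scores, and reports alpha,
Loevinger scalability, the zero-score proportion and a 52-pair test-retest
ICC — the table-style summary a scale-validation report would print.
"""

import numpy as np

import twinscales as ts

cfg = ts.SimConfig(seed=20)
responses, pedigree, truth = ts.simulate_cohort(cfg)
ad, cf = ts.sphere21_definition()

theta = ts.rank_theta(responses, ad.items, tie_seed=0)
curves = ts.fit_item_curves(responses, theta, ad.items)
scores = ts.ml_score(responses, curves, ad.items)

rep = ts.loevinger_h(responses, ad.items)
print("anxiety-depression scale (14 items)")
print(f"  Cronbach's alpha:       {rep.alpha:.2f}")
print(f"  scale H / min Hi:       {rep.h:.2f} / {rep.min_hi:.2f}")
print(f"  pairwise Hij < 0:       {rep.n_hij_negative}")
print(f"  zero-score proportion:  {ts.zero_score_proportion(responses, ad.items):.2f}")
print(f"  IRT score range:        [{scores.min():.1f}, {scores.max():.1f}]"
      f" (all-lowest respondents sit at the -3 boundary)")

# three-month retest on 52 unrelated participants
retest, theta2 = ts.simulate_retest(truth, cfg, pedigree)
sub = responses["person_id"].sample(52, random_state=1)
t1 = scores.loc[sub]
theta2r = ts.rank_theta(retest, ad.items, tie_seed=0)
curves2 = ts.fit_item_curves(retest, theta2r, ad.items)
t2 = ts.ml_score(retest, curves2, ad.items).loc[sub]
icc, lo, hi = ts.icc_consistency(t1.to_numpy(), t2.to_numpy())
print(f"  test-retest ICC (n=52): {icc:.2f} [{lo:.2f}, {hi:.2f}]")
print()
print("Alpha near 0.86 and all pairwise Loevinger coefficients positive "
      "indicate an internally consistent, scalable item set; the ICC is "
      "attenuated below the latent retest correlation by item-level noise.")
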