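"""Differential item functioning between sexes on a common latent metric.

One item receives an injected threshold shift of 1.0 for females; the DIF
report should single it out (statistic > 0.25 with disjoint confidence
bands) while the clean items stay well below the exclusion rule.
"""

import twinscales as ts

bank = [ts.ItemSpec(item_id=i, a=1.5, b1=0.2 + 0.1 * i, b2=1.4 + 0.1 * i)
        for i in range(1, 9)]
bank.append(ts.ItemSpec(item_id=9, a=1.5, b1=0.5, b2=1.7, dif_shift={"F": 1.0}))
cfg = ts.make_config(n_mz_pairs=0, n_dz_pairs=0, n_singletons=2000,
                     item_bank=bank, seed=11)
responses, _, _ = ts.simulate_cohort(cfg)

results, median_dif = ts.compare_groups(responses, list(range(1, 10)), "sex")
print("item  DIF(step1)  DIF(step2)  item DIF  significant  excluded")
for r in results:
    print(f"{r.item_id:4d}  {r.dif_step1:10.3f}  {r.dif_step2:10.3f}  "
          f"{r.item_dif:8.3f}  {str(r.significant):>11}  {str(r.excluded):>8}")
print(f"median item DIF: {median_dif:.3f}")
print()
print("The DIF statistic is the density-weighted RMS distance between the "
      "two groups' item response step functions; an item is excluded only "
      "when it exceeds 0.25 AND the groups' 95% bands separate over a "
      "region carrying at least 10% of the latent mass.")
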