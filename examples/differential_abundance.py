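"""Per-OTU negative-binomial Wald survey with independent filtering.

Every OTU seen in at least two samples is modelled (site + sex + treatment +
sex:treatment, median-of-ratios size factors); FDR correction is then applied
only to non-rare OTUs (mean relative abundance >= 0.01%, detected in >= 5% of
samples) so that power is not wasted on hopeless tests.
"""
import numpy as np

import bloomline as bl

cohort = bl.simulate_cohort(seed=11)
results = bl.filtered_bh(bl.nb_wald_test(cohort.counts, cohort.metadata))
trt = results[results["term"] == "treatment"].set_index("otu_id")

print(f"OTUs surveyed: {len(trt)}; passing the rare-OTU filter: {int(trt['tested'].sum())}")
print(f"OTUs with q < 0.05 for treatment: {int((trt['q'] < 0.05).sum())}")
top = trt.reindex(trt["wald_z"].abs().sort_values(ascending=False).index).head(5)
print("\ntop treatment responders (coef is the natural-log fold change):")
print(top[["coef", "log2_fold", "wald_z", "q", "mean_rel_abund"]].round(4).to_string())
print(f"\nexpected marginal bloom coefficient ~ (2/3)*ln(4.3) = {np.log(4.3) * 2 / 3:.3f}")
print("OTU-1 blooms at two of three sites, so its cohort-wide coefficient sits near")
print("two thirds of the planted log fold; other Muribaculaceae show negative folds.")
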