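"""Generate a synthetic multi-site acarbose cohort and inspect its planted structure.

The generator emulates a 3-site x 2-sex x 2-treatment mouse study (12 mice per
cell): OTU read counts with a Sphingopyxis spike-in, a site-dependent bloom OTU
(4.3-fold under treatment), depressed other Muribaculaceae (0.5-fold),
taxon-coupled metabolites, and SCFA-coupled lifespans with left truncation.
"""
import numpy as np

import bloomline as bl

cohort = bl.simulate_cohort(seed=42)
meta = cohort.metadata
print(f"cohort: {len(meta)} mice, {cohort.counts.shape[1]} OTUs")
print(meta.groupby(["site", "treatment"], observed=True).size().unstack())

treated = meta["treatment"].astype(str) == "ACA"
bloom_map = cohort.params.bloom_otu_by_site
for site in ("TJL", "UM", "UT"):
    in_site = meta["site"].astype(str) == site
    otu = bloom_map[site]
    ratio = (
        cohort.densities.loc[treated & in_site, otu].median()
        / cohort.densities.loc[~treated & in_site, otu].median()
    )
    print(f"{site}: bloom OTU {otu}, treated:control latent density ratio = {ratio:.2f}")

print(f"median spike read fraction: "
      f"{(cohort.spike_counts / (cohort.spike_counts + cohort.counts.sum(axis=1))).median():.3f}")
print(f"all deaths after sampling: {bool((meta['death_age'] > meta['sampling_age']).all())}")
print()
print("Per-site ratios should scatter around the planted 4.3-fold bloom; the spike")
print("fraction is the per-sample recovery used later for absolute abundances.")
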