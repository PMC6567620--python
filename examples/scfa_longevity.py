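"""Left-truncated Cox regression of lifespan on standardized fecal SCFAs.

Mice enter the risk set at fecal sampling (they could not have been sampled
had they died earlier), every death is observed, and effect sizes are hazard
ratios per standard deviation of concentration. Correlated acetate and
butyrate with opposing effects mask each other in single-covariate fits; the
joint model separates them.
"""
import bloomline as bl

cohort = bl.simulate_cohort(seed=2, n_per_cell=40)  # 480 mice for stable estimates
meta = cohort.metadata

med = bl.km_median(meta["death_age"], meta["treatment"].astype(str))
print(f"median lifespan: control {med['control']:.0f} d, ACA {med['ACA']:.0f} d "
      f"({bl.percent_change(med['control'], med['ACA']):+.1f}%)")

table = meta.rename(columns={"sampling_age": "entry", "death_age": "time"})
for s in ("propionate", "butyrate", "acetate"):
    table[s] = cohort.metabolites[s]
table["event"] = 1
res = bl.scfa_longevity_models(table)
print("\nsingle-SCFA fits over the design-only null (HR per SD):")
print(res.singles.round(3).to_string())
print("\njoint 3-SCFA fit:")
print(res.joint.round(3).to_string())
print(f"\nLRT full vs design-only: stat = {res.lrt_stat:.1f}, df = {res.lrt_df}, "
      f"p = {res.lrt_p:.2e}")
print()
print("Planted per-SD hazard ratios are 0.674 (propionate), 0.586 (butyrate) and")
print("1.576 (acetate); the joint fit should land near them while the single-fit")
print("butyrate and acetate estimates shrink toward 1 through their correlation.")
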