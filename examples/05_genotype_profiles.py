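"""Depth-profile quintile statistics for a genotype comparison.

Simulates dorsoventral marker profiles in which a mutant shifts one marker's
laminar band deeper, compresses profiles to 80 common bins, and runs the
three-way ANOVA (genotype x quintile x cell-type) with Tukey post-hoc tests
per quintile.
"""

import chronotopy as ct

cfg = ct.ProfileSimConfig(seed=4)  # markerA shifts in the mutant; markerB does not
profiles = ct.make_depth_profiles(cfg)
table = ct.quintile_weights_table(profiles, n_bins_common=80)

res = ct.quintile_stats(table)
print("three-way ANOVA (genotype x quintile x cell-type):")
print(res.anova.round(4).to_string())

hits = res.posthoc.query("p_adj < 0.05")
print("\nsignificant genotype contrasts per quintile/cell-type (Tukey, p<0.05):")
print(hits.to_string(index=False))
# The genotype x quintile interaction flags the laminar shift; the dominant
# post-hoc contrasts localize it to the superficial quintiles of the shifted
# marker (small noise-level hits can appear elsewhere).
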