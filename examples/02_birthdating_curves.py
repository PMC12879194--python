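"""Cumulative EdU birthdating curves and half-maximal birthdates.

Simulates three neuron families with staggered Gaussian birth waves, builds
litter-level cumulative co-labeling curves, fits 4PL sigmoids, and tests
whether inflection points differ between families.
"""

import chronotopy as ct

cfg = ct.BirthSimConfig(
    families={
        "early": ct.BirthWave(11.0, 0.4),
        "mid": ct.BirthWave(11.5, 0.4),
        "late": ct.BirthWave(12.0, 0.4),
    },
    seed=1,
)
counts = ct.make_birth_counts(cfg)
curves = ct.cumulative_curves(ct.colabel_fractions(counts))

final = curves.replicates.groupby("family").apply(
    lambda g: g.loc[g.timepoint == g.timepoint.max(), "cumulative_percent"].mean(),
    include_groups=False,
)
print("mean cumulative % at final pulse (pinned to 100 by construction):")
print(final.round(6).to_string())

fits = ct.fit_family_curves(curves, model="4PL")
print("\nfamily  configured-center  fitted-half-max  model  R^2")
for fam, wave in cfg.families.items():
    f = fits[fam]
    print(f"{fam:6s}  E{wave.mu_birth:<16.2f} E{f.half_max:<15.3f} {f.model_used}  {f.r_squared:.4f}")

tests = ct.inflection_tests(ct.replicate_fits(curves, model="logistic"))
print("\npairwise inflection tests (BH-adjusted q):")
print(
    tests.query("statistic == 'xmid'")[["family_a", "family_b", "t", "p", "q"]]
    .to_string(index=False)
)
# Half-max times recover the configured birth-wave centers; well-separated
# waves make every pairwise inflection comparison significant.
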