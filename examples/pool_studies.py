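"""Random-effects pooling of several prevalence studies for one age band.

Three studies report the same quantity with different precision; the
DerSimonian-Laird random-effects model pools them, allowing for
between-study heterogeneity (tau^2 > 0 widens the pooled CI relative to a
fixed-effect pool).
"""

from hivncd import StudyEstimate, pool_random_effects

Z = 1.96
studies = []
for name, p, se in [("survey A", 0.10, 0.02),
                    ("survey B", 0.20, 0.03),
                    ("survey C", 0.16, 0.025)]:
    studies.append(StudyEstimate(18, None, p, p - Z * se, p + Z * se,
                                 source_id=name))
    print(f"{name}: {p:.3f} (95% CI {p - Z * se:.3f}-{p + Z * se:.3f})")

pooled = pool_random_effects(studies)
print(f"\npooled: {pooled.point:.3f} (95% CI {pooled.ci_low:.3f}-{pooled.ci_high:.3f})")
print("The pooled point lies between the study extremes; its CI reflects both")
print("within-study error and the estimated between-study variance.")
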