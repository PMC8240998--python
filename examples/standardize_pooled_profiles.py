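"""Direct age-standardization of pooled age-specific prevalence profiles.

Builds the pooled adult hypertension and diabetes profiles and the cervical
HPV profile (ages 15+), standardizes each against the WHO World Standard
Population, and prints the age-standardized prevalence (ASP).  The ASP is the
prevalence the population would have if its age structure matched the WHO
standard, which makes values comparable across populations with different
age pyramids.
"""

from hivncd import PooledAgeProfile, StudyEstimate, direct_standardize

ADULT = [(18, 30), (30, 40), (40, 50), (50, 60), (60, None)]
CERVICAL = [(15, 25), (25, 30), (30, 35), (35, 40), (40, None)]

profiles = {
    "hypertension (18+)": (ADULT, 18, [13.8, 18.9, 29.6, 42.6, 52.5]),
    "type 2 diabetes (18+)": (ADULT, 18, [1.6, 2.7, 4.6, 5.8, 7.6]),
    "cervical HPV, overall (15+)": (CERVICAL, 15, [31.9, 32.9, 29.1, 33.8, 28.0]),
}

for name, (bands, lower, pct) in profiles.items():
    ests = [StudyEstimate(lo, hi, v / 100) for (lo, hi), v in zip(bands, pct)]
    prof = PooledAgeProfile(ests, lower_age_bound=lower)
    asp = 100 * direct_standardize(prof)
    print(f"{name}: age-specific {pct} %  ->  ASP {asp:.1f} %")

print("\nEach ASP is a convex combination of the band values, weighted by the")
print("WHO standard age distribution collapsed onto the profile's bands")
print("(partial 5-year bands pro-rated linearly, e.g. 18-19 = 2/5 of 15-19).")
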