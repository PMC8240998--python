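# Methods

This note documents the model structure, the defaults and why they were
chosen, what the synthetic fixtures do and do not emulate, and the numerical
choices a user should know before trusting or extending results.

## Evidence synthesis

**Pooling.** Study estimates of one age band are pooled with
DerSimonian–Laird random effects on the reported scale (proportion or rate
per 100,000 person-years; mixing scales is an error). The within-study
variance is (CI half-width / 1.96)² when a 95% CI is reported, else the
binomial approximation p(1−p)/n. Between-study variance τ² is the moment
estimator floored at zero. The normal approximation on the proportion scale
(no logit or arcsine transform) was chosen because it reproduces published
pooled values at the 1-decimal precision they are printed with; for
proportions near 0 or 1 a transform would behave better and the pooled CI is
clipped to [0, 1]. A single study is returned unchanged.

**Direct age standardization.** The embedded standard is the WHO World
Standard Population (2000–2025 revision), 5-year bands to 85+. Profile
bands rarely align with 5-year edges, so standard weights are collapsed onto
the profile's bands with *linear pro-rating* of partial bands (ages 18–19
contribute 2/5 of the 15–19 weight) and renormalized over the profile's
support: 18+ for adult conditions, 15+ for cervical outcomes. These two
lower bounds are the convention under which the published standardized
values are reproduced exactly at 1 decimal; band-level recomputation of the
published stroke incidence ASI does not reproduce it (we obtain ≈112 vs a
printed 114.8 per 100,000, presumably because the original used the source
study's finer age structure), so stroke ASI is reported but not treated as a
reproduction check.

## The simulator

**Time and ordering.** Discrete time, default step 1/12 year. A step
applies, in fixed order: HIV incidence; CD4 progression and ART initiation;
cervical transitions; chronic-NCD and cancer onsets; depression episodes;
CVD events with acute case fatality; all-cause mortality; births; aging.
Mortality runs after onsets so a same-step onset can already raise death
risk; this ordering is a documented discretization choice, not an inference.
Hazards convert to per-step probabilities as 1 − exp(−hΔ); with the monthly
default, discretization error against the exponential closed form is well
inside Monte Carlo noise at the tested sizes. The population is closed (no
migration); one agent represents `scale_factor` persons in reported counts.

**Randomness.** One master seed; per-run sub-seeds and per-module substreams
(initialization, HIV, ART, cervical, NCD onsets, depression, CVD, mortality,
births) spawned via `numpy.random.SeedSequence`. Same seed ⇒ byte-identical
event logs; because modules own their streams, perturbing one disease leaves
the draw sequences of unlinked modules untouched, which the tests exploit.

**HIV.** Incidence is an input rate (no transmission dynamics). CD4 is
continuous: Normal at seroconversion (mean 570 cells/µL at age 25, −2/year
of age, SD 150, floored at 50), linear decline off ART (62 male / 56 female
cells/µL/yr), recovery at 80 cells/µL/yr toward a 650 plateau on ART. These
natural-history defaults are plausible regional values and fully
configurable; the mortality lookup uses strata ≥500 / 350–499 / 200–349 /
<200 with ART-naive multipliers (1.5, 2.5, 5, 15) on background mortality,
of which 50% of the excess is retained on ART < 2 years and 20% on long-term
ART (floor 1). 90-90-90 is operationalized as 0.9³ ≈ 73% of PLWH on ART by
2020, held constant after; there is no ART discontinuation. Initiation
prioritizes the lowest CD4 among the year's eligible.

**NCDs.** Baseline onset hazards are log-linear in age with an optional sex
offset, zero below a condition-specific minimum age. Hazard-ratio modifiers
(comorbidity and HIV) combine multiplicatively — the standard
proportional-hazards convention for joint effects. The IHD hazard is 4× the
stroke hazard of the same individual; by default the stroke comorbidity
modifiers (diabetes ×2.431, hypertension ×1.426) scale the IHD component
too, since both are CVD outcomes of the same risk process — a toggle
(`apply_stroke_modifiers_to_ihd=False`) restricts them to the stroke
component. Only the first CVD event is modeled; survivors carry the chronic
excess death risk. Depression recurs; the default episode duration is 6
months (a model assumption, configurable), and reported depression
prevalence is 12-month period prevalence. High total cholesterol is an
onset-only chronic state with no direct mortality and, by default, no
hazard into CVD.

**Mortality and cause attribution.** The death hazard is background μ(age,
sex, period) × HIV multiplier × the product of excess relative risks of the
fatal conditions present. On death, the cause is "background" with
probability μ/total, and otherwise one of the contributing factors with
probability proportional to (rᵢ − 1) — for a single factor r this gives the
intuitive (rμ − μ)/rμ. Hypertension, high total cholesterol and depression
are never independent causes of death. Stroke and IHD additionally carry an
instantaneous case-fatality probability at the event.

**Cervical natural history.** Five stages (susceptible ↔ HPV → CIN2/3 → CIS
→ cancer, cancer absorbing), CIN1 not modeled separately, no post-clearance
immunity (reinfection allowed). Transitions out of a stage are competing
exponentials discretized to the step. A stage entered in the current step
cannot be left until the next step, which prevents multi-stage jumps within
one Δ. The HIV modifiers apply to women HIV-positive and ART-naive or on
ART < 2 years; on ART ≥ 2 years behaves as HIV-negative.

## Calibration

Log-linear (intercept, slope) per NCD, fitted by Nelder–Mead minimizing
Σ wᵢ (simᵢ − obsᵢ)² with wᵢ = 1/(CI half-width)², simulated with common
random numbers (fixed sub-seeds per evaluation) so the objective is a
deterministic function of the parameters and accepted-iteration loss is
non-increasing. Excess death risks are parametrized as 1 + exp(θ) (so RR ≥ 1
throughout) and fitted to cause-of-death fractions; a target fraction of
zero pins the RR at 1. Because the simulated fractions are step functions
of the RRs at finite n, the optimizer uses a generously spread initial
simplex. Non-convergence inside the iteration budget returns a flagged
result rather than raising. Calibration is validated by parameter
*recovery* on fixture targets (truth exists by construction), not by
matching any published fitted values, which are not public.

## Synthetic fixtures

The fixture generator emulates: a young age pyramid (exp(−0.035·age) in
1950), fertility declining from TFR 7.5 toward a floor of 3.4, background
mortality declining ~0.8%/yr (population grows ≈6 M → ≈46 M at the default
scale over 1950–2018, mean age ≈22–23); an HIV epidemic starting 1980,
peaking mid-1990s and plateauing so adult (15+) prevalence is ≈3–4% in 2018
with female incidence 1.6× male; ART ramping from 2004 to 73% coverage by
2020 with historically tightening CD4 eligibility (200 → 350 → 500 →
treat-all); NCD truth hazards at magnitudes comparable to the pooled survey
estimates (hypertension prevalence rising ≈14% → 52% across adult bands,
diabetes in the low single digits, stroke incidence hundreds per 100,000 at
older ages); cervical rates giving ≈30% HPV and mid-single-digit CIN2/3
prevalence in women.

It does **not** emulate: real vital-registration or programme data (all
rates are smooth parametric stand-ins), migration, HIV transmission
feedback, NCD treatment cascades, or lifestyle risk factors. Passing tests
therefore demonstrate that the *machinery* is correct — conservation,
closed-form limits, modifier arithmetic, calibration recovery,
stratification logic — not that any headline burden number is a valid
estimate for a real country. Producing real estimates requires replacing
the fixture files with actual surveillance inputs in the same formats.

Default problem sizes were chosen for desk-scale runtime with acceptable
Monte Carlo error: 50,000 initial agents (≈120 persons/agent) for single
validation runs, 1,500–20,000 agents for replicate-based property checks,
100 replicates for averaging, and quarterly steps where the monthly default
is not needed for the quantity under test.

## Known limitations

* The normal-scale pooling and CI clipping are crude near boundary
  proportions.
* Cause-of-death attribution shares the excess proportionally to (r − 1);
  other conventions (e.g. log-hazard shares) would attribute multi-morbidity
  deaths differently.
* Mortality selection couples conditions across HIV strata: even an NCD with
  no HIV hazard ratio (diabetes) shows a slightly *lower* age-standardized
  prevalence in PLWH because its excess mortality compounds with the HIV
  multiplier. This is a real property of multiplicative-hazards models, and
  the stratified comparisons in the tests account for it.
* ART coverage targets are enforced against the current PLWH denominator
  each step; during fast epidemic growth observed coverage trails the
  schedule within the year.
* The calibrator fits one NCD at a time; joint fitting of interacting
  conditions (e.g. diabetes and hypertension feeding CKD) must iterate.
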