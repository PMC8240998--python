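# hivncd

An individual-based (agent) microsimulation of noncommunicable-disease (NCD)
burden in a generalized-HIV-epidemic setting, together with the
evidence-synthesis tools used to parameterize and report such a model:
DerSimonian–Laird random-effects pooling of survey estimates and direct age
standardization against the WHO World Standard Population.

It is written for epidemiological modellers who need country-level estimates
and projections of multimorbidity by HIV status — how many adults live with
one or more of hypertension, high total cholesterol, type 2 diabetes, chronic
kidney disease (CKD), depression, cardiovascular disease (CVD) or cancer, and
how that burden differs between people living with HIV (PLWH) and the
HIV-negative population as both grow and age.

## The model

Each simulated individual carries sex, date of birth, vital status, HIV state
(seroconversion date, continuous CD4 count, ART status), per-NCD onset dates,
recurrent depressive episodes, at most one lifetime CVD event, and — for
women — a cervical HPV → CIN2/3 → CIS → cervical-cancer natural-history
stage. Time advances in discrete steps (monthly by default); every hazard
*h* becomes a per-step event probability 1 − exp(−*h*Δ).

* **Demography.** Births from age/period fertility rates, deaths from
  age/sex/period background mortality; rates decline over calendar time as in
  a young, growing population.
* **HIV.** Incidence is an exogenous age/sex/year rate (held at its final
  observed level in projection). CD4 declines linearly off ART, recovers on
  ART; ART initiation ramps to the 90-90-90 treatment level (0.9³ ≈ 73% of
  PLWH) and prioritizes low CD4. HIV multiplies background mortality by a
  CD4-stratum factor, attenuated with time on treatment.
* **NCDs.** Onset hazards are log-linear in age, multiplied by published
  hazard ratios for pre-existing conditions and HIV (e.g. stroke given
  diabetes ×2.431, CKD given hypertension ×1.469, CKD given HIV ×2.04,
  depression given HIV ×3.1). IHD incidence is 4× the stroke hazard; both
  carry an acute case fatality and only the first CVD event is modeled.
  Each fatal condition applies a fixed excess relative risk to background
  mortality, and the cause of death is attributed in proportion to each
  factor's excess contribution. Hypertension, high total cholesterol and
  depression are never independent causes of death.
* **Cervical cancer** arises only through the HPV/CIN pathway; women with
  HIV who are ART-naive or on ART < 2 years have HPV acquisition ×1.63,
  clearance ×0.52 and HPV→CIN2/3 progression ×1.32, so their excess cancer
  risk is emergent.
* **Calibration.** Baseline age-hazards and excess death risks are inferred
  from age-band prevalence/incidence targets and cause-of-death fractions by
  weighted least squares with Nelder–Mead over log-parameters, using common
  random numbers so the stochastic objective is deterministic in the
  parameters.
* **Evidence synthesis.** `pool_random_effects` pools study estimates per
  age band (DerSimonian–Laird); `direct_standardize` computes the
  age-standardized prevalence ASP = Σᵢ wᵢ pᵢ with WHO-standard weights wᵢ
  collapsed onto the profile's bands (partial 5-year bands pro-rated
  linearly; adult profiles standardized over 18+, cervical over 15+).

Real applications are driven by national vital statistics, programme HIV
estimates and burden-of-disease death fractions supplied as delimited
parameter files. The `synthetic` module generates a self-contained, stylized
stand-in fixture (Kenya-like growth, ~3% adult HIV prevalence, rising-with-age
NCD targets with known ground truth) so every stage runs and is testable
without external data.

## Worked example

`python examples/standardize_pooled_profiles.py` standardizes pooled
age-specific prevalence profiles:

```
hypertension (18+): age-specific [13.8, 18.9, 29.6, 42.6, 52.5] %  ->  ASP 28.7 %
type 2 diabetes (18+): age-specific [1.6, 2.7, 4.6, 5.8, 7.6] %  ->  ASP 4.0 %
cervical HPV, overall (15+): age-specific [31.9, 32.9, 29.1, 33.8, 28.0] %  ->  ASP 30.1 %
```

Each ASP is the standard-weighted mean of the band values: the prevalence the
population would show if it had the WHO standard age structure.

`python examples/run_fixture_projection.py` runs the full model on the
synthetic fixture (8,000 agents, quarterly steps) and prints, among others:

```
2018: population 46.4 M, HIV prevalence 15+ 3.6%, ART coverage 59%
2018: adults with >=1 NCD  all 45% | PLWH 66% | HIV-negative 44%
2035: adults with >=1 NCD  all 47% | PLWH 71% | HIV-negative 46%
```

The PLWH excess is driven by their older age profile plus the HIV hazard
ratios; absolute counts double with population growth even though prevalence
moves little. (Fixture outputs are demonstrative — the fixture is stylized,
not fitted to any country's data.)

The other examples show pooling (`pool_studies.py`), calibration by
parameter recovery (`calibrate_recovery.py`) and the cervical equilibrium by
HIV status (`cervical_equilibrium.py`). A thin CLI mirrors the pipeline:
`hivncd pool|standardize|make-fixtures|simulate|calibrate|report`.

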