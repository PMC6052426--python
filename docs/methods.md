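# Methods

## Model overview

`vtece` implements a Markov cohort state-transition model of anticoagulation
for venous thromboembolism (VTE), comparing edoxaban (a NOAC) with warfarin
(a VKA) from a UK NHS perspective. A closed cohort enters at the index VTE
event (a DVT and/or PE) already initiated on treatment, and transitions in
monthly cycles over a 50-year (600-cycle) horizon.

Eight mutually exclusive states are tracked, several with sub-strata:

* **on treatment, index episode** — months 1..6 of the initial episode;
* **on treatment after recurrence** — a 6-month stratum and a lifelong
  stratum, each with a within-episode month clock;
* **off treatment**;
* **recurrent VTE**, **non-ICH major bleed**, **ICH** — one-cycle tunnel
  states carrying the acute utility decrement and acute cost, resolved into
  death / re-treatment / off-treatment at the end of their cycle;
* **death** (absorbing).

Clinically relevant non-major bleeds (CRNMB) do not interrupt
anticoagulation, so they are carried as a one-cycle *overlay* on the
continuing treatment state (event cost and a 5% relative utility decrement
for that cycle) rather than as a separate exclusive state. Overlay members
remain exposed to that cycle's event risks; the mass balance of the
exclusive states is unaffected.

Three long-term conditions are concomitant prevalence trackers, carried
alongside the exclusive states: severe post-thrombotic syndrome (PTS, after
DVT), chronic thromboembolic pulmonary hypertension (CTEPH, after PE) and
disability following ICH. Both are permanent once acquired.

## Event risks and the time stratification

Monthly baseline probabilities (warfarin arm) for VTE recurrence, CRNMB,
non-ICH major bleeding and ICH are stratified into the *first six months
after first anticoagulant initiation* versus *following months*, matching
the time-split of the underlying trial analysis. The stratum therefore
follows **calendar time since model entry**, not a per-episode clock: a
re-treatment episode started in year 3 faces the "following months" rates.
(Restarting the elevated stratum at every re-treatment compounds the
first-six-month rates over a lifetime of recurrences and roughly triples
cumulative bleed counts; the calendar clock is the reading consistent with
the published cumulative incidences.)

Edoxaban probabilities are derived from the warfarin baselines through the
odds transform p' = OR·p / (1 − p + OR·p), since odds ratios act on odds;
for these small monthly probabilities the transform is numerically close to
a rate ratio. Competing events within a cycle are mutually exclusive
categorical draws; probabilities are used directly, and the engine raises an
error (naming the stratum) if they could sum above 1 — silent rescaling
would hide bad inputs.

Off treatment, the only event is recurrence at 0.42% per month, for life.

## Treatment episodes, tertiary prevention and maintenance

* **Initial episode**: 6 months on the randomised drug (arm-specific risks,
  costs and the warfarin utility decrement).
* **After a recurrence** (tertiary prevention): survivors re-initiate
  anticoagulation; 28% (those with both an index and a recurrent PE) are
  treated lifelong, the rest for 6 months. The first 6 months of any
  re-treatment episode — the window the trial informs — are arm-specific
  (risks via the odds ratios, the arm's cycle costs, the warfarin
  decrement).
* **Lifelong maintenance** beyond that window is modelled as a common,
  fully protective long-term strategy in both arms: no further modelled
  recurrences or bleeds, a NOAC-like monthly drug cost identical in both
  arms, no INR monitoring and no arm-specific utility decrement. Only
  background and concomitant-condition mortality apply. This keeps the
  arms' long-term trajectories comparable where the trial provides no
  arm-specific evidence, and reproduces the published result that the
  later-period odds ratios contribute little to the incremental outcomes.
* Patients discontinuing after a major bleed (ICH or non-ICH) stay off
  treatment until the next recurrence.

## Mortality

Background mortality comes from a life table by age and sex, mixed by the
cohort's sex split (57% male by default) and converted to a monthly
probability via p = 1 − (1 − q)^(1/12). Cohort age advances
deterministically (age = entry age + cycle/12, truncated to integer ages).
Disease-specific mortality is additive within a cycle: case fatality at the
event cycle (PE recurrence 6.1% applied to the PE share of recurrences;
non-ICH MB 6.1%; ICH 26.1%; perioperative endarterectomy 4.4%), and
long-term monthly excess mortality for post-ICH disability (3.3%) and CTEPH
(0.7%). Tracker members are assumed spread proportionally across the alive
states: they die of other causes at the population-average rate and their
excess deaths are removed from the alive states proportionally. The small
overlap between trackers (e.g. PTS members dying of CTEPH) is ignored.

### The synthetic life table

A Gompertz–Makeham law per sex (annual hazard λ + a·e^{b·age}; defaults
λ = 5·10⁻⁴, male a = 3.4·10⁻⁵, b = 0.095, female a = 1.2·10⁻⁵, b = 0.101)
stands in for official national life tables so that the package runs with
no downloads. The coefficients approximate contemporary UK rates (life
expectancy from age 56 of roughly 27 years for men and 31 for women).
A literal CSV (`age,sex,qx`) can be supplied instead. Because the published
analysis does not state its life-table edition or the cohort's entry
age/sex (defaults here: 56 years, 57% male), *absolute* life-year and QALY
totals are approximate; the incremental results that the tests check are
insensitive to modest background-mortality error. This is the main respect
in which the synthetic inputs are weaker than the real analysis: passing
tests demonstrate internally consistent incremental arithmetic, not a
replication of absolute survival.

## Sequelae

Per event, CTEPH incidence is 4.8% × (fraction of the event mix with PE)
and severe-PTS incidence 2.7% × (fraction with DVT). An event carrying both
PE and DVT contributes to both, so the DVT fraction includes PE-with-DVT:
for the index mix, f_DVT = (1 − p_PE) + p_PE·p_PE+DVT = 0.776; for
recurrences, 0.684. Index-event sequelae are applied at model entry. At
CTEPH onset 50.3% undergo pulmonary endarterectomy (perioperative mortality
4.4%); all CTEPH patients then carry £1,348/month drug costs, 0.7% monthly
mortality and a 30% utility decrement for life.

## Utilities

The index-VTE state utility is the DVT/PE-weighted 0.599×0.71 + 0.401×0.67
≈ 0.694, used as the baseline for every alive state. Relative decrements
multiply it: warfarin treatment 1.37% (initial and re-treatment episodes,
warfarin arm), the acute event cycle (CRNMB 5%, non-ICH MB 31.58%, ICH
65.26%, recurrence first month 14%), and the concomitant conditions (PTS
13.68%, CTEPH 30%, post-ICH disability 65.26%) — all multiplicative, as a
cohort expectation ∏(1 − dᵢ·πᵢ) over the tracker prevalences πᵢ. Death
contributes zero. A piecewise-constant general-population age norm (0.94
under 25 falling to 0.73 at 75+) acts as a ceiling on state utilities; at
the base inputs the VTE state utility 0.69 is below every norm, so the
ceiling only binds in sensitivity draws with high state utilities. A flag
(`apply_age_ceiling=False`) disables it.

## Costs (GBP, NHS reference costs)

Per-cycle treatment costs are stored as the published primitives — warfarin
£273.81 first cycle / £26.73 after, edoxaban £108.62 / £53.27 — because the
printed components do not reconcile exactly with them. For sensitivity
analyses that perturb a *component* (heparin £12.82/day × 6.5 or 5.0 days,
INR visits £87 first / £26 subsequent, 4 titration visits, 1 monthly visit,
drug prices), cycle costs move by the component delta relative to the
packaged decomposition, so base values always reproduce the primitives.
The warfarin first cycle is split £191 INR (87 + 4×26) / £82.81 other for
reporting; subsequent cycles £26 / £0.73.

Category bookkeeping mirrors the published results table: the *treatment*
and *INR monitoring* categories cover the initial episode only (INR in the
warfarin arm only); all treatment after a recurrence — the arm's episode
costs (heparin lead-in at re-initiation; the titration block is not
repeated) plus the common maintenance drug cost — is booked with the
recurrence category, together with acute recurrence costs (exclusive mix:
0.565×£1,647 + 0.435×£551 ≈ £1,170). Acute bleeds cost £384 (CRNMB),
£2,940 (non-ICH MB), £3,012 (ICH); post-ICH disability £524/month; PTS £168
first month then £23/month; CTEPH as above (first-month expectation
0.503×£7,824 + £1,348 ≈ £5,283).

Costs and QALYs accrue at the start of their cycle and are discounted at
3.5%/year via (1.035)^(−cycle/12); no half-cycle correction is applied.
With a zero-month horizon only the first-cycle treatment cost accrues.

## Comparative statistics

Incremental values are edoxaban minus warfarin. NMB = ΔE·λ − ΔC holds
exactly by construction; "dominant" means ΔE > 0 and ΔC < 0, and an ICER is
reported only when the signs agree.

## Sensitivity analyses

* **One-way (tornado)**: each parameter with a published range is set to
  its low and high bound in turn (two full two-arm runs each); rows are
  sorted by NMB span, ties broken lexicographically. Parameters without
  bounds are skipped with a logged warning.
* **Probabilistic**: every parameter with a range is sampled independently
  per draw — beta for probabilities/proportions/utilities (mean = base,
  sd = range/3.92), log-normal for odds ratios (median = base, the printed
  interval as the 95% CI), gamma for costs and resource counts (mean =
  base, sd = range/3.92); degenerate ranges become point masses. The
  distribution families are a modelling choice; the published analysis
  states only that "appropriate" distributions were used. 2,000 draws by
  default, all randomness through one seeded generator; invalid draws are
  resampled (capped at 100 retries, logged).
* **CEAC**: fraction of draws with ΔE·λ − ΔC > 0 over a λ grid. The NMB
  interval is the 2.5/97.5 percentile range of the draws.

## Scenario and subgroup analyses

Named experiments: `base`, the four index-event subgroups (`dvt_only`,
`pe_any`, `pe_only`, `pe_plus_dvt` — implemented by overriding the index
PE / PE-with-DVT fractions, whose pooled sensitivity bounds are dropped),
and three scenarios (`or_nonsig_to_one`, which sets exactly the odds ratios
whose CIs include 1 to 1.0; `horizon_1y`; `horizon_5y`). Subgroups reuse
the pooled recurrence mix, event probabilities and odds ratios — the source
analysis provides no subgroup-specific rates — which limits fidelity for
the PE subgroups, whose published incremental QALYs (0.043–0.046) exceed
what a pooled recurrence mix can produce (~0.031); dominance is preserved
in all four.

## Numerical choices and degenerate inputs

Mass conservation is asserted every cycle at 1e−9. Tracker prevalences are
capped at the alive fraction. Aggregate odds ratios cannot be applied to
p = 1 (error). The engine is pure scalar arithmetic per cycle (a ~24-state
vector), making a 600-cycle two-arm evaluation run in ~25 ms and the
2,000-draw PSA in under a minute on one CPU; these defaults are the study
sizes used throughout the tests and the acceptance script.

## Known limitations

* Entry demographics and the life table are stand-ins (see above).
* Two published sensitivity ranges do not bracket their base values
  (non-ICH-MB later-months OR, DVT event cost); the offending bound is
  clipped to the base value.
* The recurrence-differential channel (fewer early recurrences under
  edoxaban, with downstream CTEPH, maintenance-treatment and mortality
  streams) makes the model's incremental costs more favourable to edoxaban,
  and more variable across probabilistic draws, than the published
  headline; the published scenario analysis implies that channel was
  largely absent from the original implementation, but removing the
  recurrence odds ratios would contradict the published inputs and degrade
  every incremental outcome. See the scenario results for the magnitude.
* No provoked/unprovoked distinction, no microsimulation, no EVPI.
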