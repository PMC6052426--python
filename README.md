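# vtece

A Markov cohort cost-effectiveness model of **edoxaban vs. warfarin** for
the treatment and secondary prevention of venous thromboembolism (VTE),
from the UK NHS perspective. It is written for health economists and
methodologists who want a fully scripted, testable implementation of this
class of anticoagulation decision model: base-case evaluation, scenario and
index-event subgroup analyses, one-way (tornado) and probabilistic
sensitivity analysis with cost-effectiveness acceptability curves.

## The model in brief

A cohort enters at an index DVT and/or PE, on anticoagulation, and moves in
monthly cycles over a lifetime (50-year) horizon through eight exclusive
states — on treatment (index episode), off treatment, recurrent VTE, on
treatment after recurrence (6-month or lifelong), clinically relevant
non-major bleed, non-ICH major bleed, intracranial haemorrhage, death —
plus three concomitant long-term conditions (severe post-thrombotic
syndrome, CTEPH, post-ICH disability). Monthly event probabilities are
stratified into the first six months after treatment initiation vs. later
months; edoxaban's risks come from the warfarin baselines through trial
odds ratios via the odds transform p' = OR·p/(1−p+OR·p). Costs and QALYs
are discounted at 3.5%/year and compared as

    ΔE = E_edox − E_warf,  ΔC = C_edox − C_warf,  NMB = ΔE·λ − ΔC

at a willingness-to-pay λ = £20,000/QALY; edoxaban is *dominant* when
ΔE > 0 and ΔC < 0. Model structure, parameter values and conventions are
documented in [docs/methods.md](docs/methods.md).

## Worked example

```python
import vtece

params = vtece.base_case_parameters()        # packaged published inputs
model  = vtece.MarkovCohortModel(params)
result = model.evaluate()                    # runs both arms, ~25 ms
print(result.summary())
```

prints

```
Cost-effectiveness of edoxaban vs. warfarin
=======================================================
                                Edoxaban    Warfarin
Life years                        15.774      15.742
Total QALYs                       10.838      10.806
Total costs                        7,557       7,631
  treatment                          359          86
  inr                                  0         312
  rvte                             2,591       2,552
  crnmb                               35          44
  non_ich_mb                          34          32
  ich                                  8          28
  complications                    4,530       4,577
-------------------------------------------------------
Incremental QALYs:  0.032
Incremental LY:     0.032
Incremental costs:  -74 GBP
ICER:               Dominant
NMB @ 20,000/QALY: 715 GBP
```

Edoxaban gains ~0.032 QALYs per patient and saves ~£74: its higher drug
cost (treatment row) is outweighed by avoided INR monitoring and fewer
bleeds, so it dominates warfarin. (Absolute life-year/QALY totals depend on
the synthetic life table and assumed entry demographics; the incremental
rows are the meaningful output.)

Sensitivity analyses hang off the same parameter set:

```python
rows = vtece.one_way_dsa(params)                      # tornado
psa  = vtece.run_psa(params, n=2000, seed=1)          # probabilistic
print(psa.summary()["fraction_dominant"])
```

## Command line

```sh
vtece fixture --out inputs/                 # emit base_case.yaml + life table
vtece run --params inputs/base_case.yaml --out results/
vtece dsa --params inputs/base_case.yaml --out results/ --plot
vtece psa --params inputs/base_case.yaml --n 2000 --seed 1 --out results/ --plot
vtece report --results results/ --out results/report.md
```

`run` executes the named experiment bundles (base case, four index-event
subgroups, odds-ratios-to-1 scenario, 1- and 5-year horizons) and writes a
results table per experiment; every command writes a manifest with the
parameter-file hash and seed.

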