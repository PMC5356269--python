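# csfcea

Lifetime cost-effectiveness analysis of cerebrospinal-fluid (CSF) biomarker
testing for the diagnosis of Alzheimer's disease (AD) in patients who remain
without a definitive diagnosis after clinical assessment and MR neuroimaging.

## What it models

Patients referred with suspected dementia are first evaluated clinically and
by MRI. For the residual undiagnosed cohort (pretest AD prevalence 12.7% in
the base case), the package compares **biomarker analysis** — a lumbar
puncture costing $463 with a one-time 0.008 QALY toll, classifying each
patient as true/false positive/negative with conditional sensitivity 0.698
and specificity 0.941 — against **doing nothing**. Each diagnostic outcome
group then moves through a monthly-cycle Markov cohort model: AD patients
across 12 health states (mild/moderate/severe x community/long-term-care
facility x on/off treatment), non-AD patients across 4, with death absorbing.
Diagnosed patients receive donepezil (memantine in severe AD), which slows
progression (hazard ratio 0.5 mild->moderate), promotes regression (x2.36
moderate->mild), and delays facility entry (x0.37), but never affects
mortality. Lifetime costs (2013 US$, societal perspective), QALYs, and
life-years are discounted at 3%/yr and combined into the incremental
cost-effectiveness ratio

    ICER = (C_biomarker - C_do-nothing) / (Q_biomarker - Q_do-nothing),

judged against willingness-to-pay thresholds of $50,000 and $100,000 per
QALY. The package also provides one-way/two-way deterministic sensitivity
analysis, prevalence-threshold search, structural scenarios, a 10,000-draw
probabilistic sensitivity analysis with cost-effectiveness acceptability
curves, the Phelps–Mushlin "challenge region" for hypothetical tests via the
incremental net monetary benefit identity, and an individual-level
microsimulation that cross-validates the cohort engine.

See `docs/methods.md` for model structure, conventions, and limitations.

## Worked example

```python
from csfcea import load_parameters, run_pipeline, prevalence_threshold

ps = load_parameters()          # packaged base-case inputs
res = run_pipeline(ps)

for g, o in res.outcomes.items():
    print(f"{g}: cost ${o.discounted_cost:,.0f}  QALYs {o.discounted_qalys:.3f}"
          f"  LYs {o.life_years:.3f}")
inc = res.incremental
print(f"incremental: ${inc.delta_cost:,.0f} for {inc.delta_qalys:.4f} QALYs"
      f" -> ICER ${inc.icer:,.0f}/QALY")
print(f"$50k threshold prevalence: {100 * prevalence_threshold(50_000, ps):.1f}%")
```

prints

```
TP: cost $284,699  QALYs 3.009  LYs 6.786
FN: cost $293,817  QALYs 2.765  LYs 6.560
FP: cost $270,195  QALYs 5.041  LYs 9.155
TN: cost $258,856  QALYs 5.041  LYs 9.155
incremental: $239 for 0.0136 QALYs -> ICER $17,579/QALY
$50k threshold prevalence: 9.9%
```

Reading: an accurate diagnosis (TP vs FN) saves ~$9,100 and gains 0.24
QALYs per AD patient; a false positive (FP vs TN) wastes ~$11,300 in
treatment costs without affecting survival or quality of life. At 12.7%
pretest prevalence the test adds $239 and 0.0136 QALYs per patient — firmly
cost-effective at $50,000/QALY — and becomes outright cost-saving above
~16% prevalence.

The same analyses are available from the shell:

```sh
csfcea run                      # per-outcome / per-strategy table
csfcea cohort                   # diagnostic-algebra quantities
csfcea threshold --wtp 50000
csfcea psa --n 10000 --seed 1
csfcea challenge --wtp 50000
csfcea microsim --group TP --n 50000
```

Every run writes CSV/JSON results plus a manifest (config digest, seed,
version) under `--out`.

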