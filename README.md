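# gtbias

Guarantee-time bias (also called immortal-time or time-dependent bias) is a
classic pitfall of pharmacoepidemiologic cohort studies: to become a drug
user — and even more so a *high cumulative dose* user — a subject must have
survived event-free long enough to initiate and accumulate the drug. A
time-fixed Cox regression that attributes the whole follow-up to the final
exposure group credits that guaranteed event-free time to the drug, and the
drug appears protective even when it does nothing.

`gtbias` is a toolkit for studying and avoiding this bias. It provides:

- a **discrete-time cohort simulator** with the bias built in: N subjects
  followed over 10 yearly intervals, a fraction of whom initiate a drug at a
  uniform random interval W and accrue a constant dose per interval,
  categorized into none/low/moderate/high cumulative-dose groups
  Z₁(t), Z₂(t), Z₃(t); the per-interval event probability is logistic,

  P(t) = expit(β₀ + β₁Z₁(t) + β₂Z₂(t) + β₃Z₃(t));

- the three competing analyses: **naive time-fixed Cox** (final dose group
  applied from time 0 — the biased design), **time-dependent Cox** on the
  counting-process expansion (exposure as a time-varying covariate), and
  **landmark Cox** (subjects event-free at a landmark time τ, exposure
  frozen at its value at τ), all fitted by Efron-corrected partial
  likelihood via `lifelines`;
- the **analytic landmark theory**: the conditional densities
  f(t | Z(τ₀)=0) and f(t | Z(τ₀)=1) = q₁(t)/Q₁(τ₀) of the residual event
  time given landmark exposure status, and a numerical verification that
  under the null (q₀ = q₁) both collapse to q₀(t)/Q₀(τ₀) for *any*
  initiation-time distribution — the identity that makes landmark
  comparisons valid;
- a **Monte-Carlo harness** aggregating type I error, power, bias and MSE of
  the estimated hazard ratios per method and dose group, with bit-exact
  reproducibility from a root seed and manifest-driven re-runs.

## Worked example

```python
from gtbias import (SimulationConfig, simulate_cohort, make_counting_process,
                    make_naive_design, fit_cox)

config = SimulationConfig(seed=1)          # null: no drug effect
subjects, long = simulate_cohort(config)
print(f"{len(subjects)} subjects, {int(subjects.event.sum())} events, "
      f"{int((subjects.final_dose_category != 'none').sum())} realized drug users")

naive = fit_cox(make_naive_design(subjects))
timedep = fit_cox(make_counting_process(long))
for g in ("low", "moderate", "high"):
    n, t = naive.estimates[g], timedep.estimates[g]
    print(f"{g:<10}{n.hr:>10.3f}{n.p_value:>10.4f}{t.hr:>10.3f}{t.p_value:>10.4f}")
```

prints

```
5000 subjects, 703 events, 235 realized drug users
low            1.029    0.9325     0.951    0.8819
moderate       0.766    0.4273     1.336    0.3902
high           0.275    0.0100     1.123    0.8181
```

The drug has no effect in this cohort, yet the naive analysis estimates a
high-dose hazard ratio of 0.275 and "significantly" rejects the null
(p = 0.01) — pure guarantee-time bias, since high-dose subjects needed ≥ 7
event-free years to reach that category. The time-dependent analysis, which
only credits exposed person-time to the exposed state, stays near HR = 1
for every group.

The same comparison at Monte-Carlo scale (type I error, power, bias, MSE
tables over three baseline incidence rates):

```sh
gtbias tables --seed 0 --reps 1000 --out-dir results/
```

The command line also exposes `simulate`, `fit` (including on external
cohort CSVs in a documented schema), `scenario` and `landmark-density`; see
`gtbias --help` and the file-format notes in `src/gtbias/io.py`.

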