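# Methods

## The data-generating process

The simulator implements a discrete-time survival model over
`n_intervals` = 10 yearly periods. Each of `n_subjects` = 5000 subjects
(default) is either a never-user or an *intended* drug user; intended users
are a simple random sample of size round(N × `intended_user_rate`), with a
default rate of 5%. Each intended user draws an initiation interval W
uniformly on {1, …, 10} and, from interval W on, accrues a constant
`dose_per_interval` = 0.5 per period, so the cumulative dose through
interval t is 0.5·(t − W + 1). Cumulative dose is categorized as
none (= 0), low (0, c₁], moderate (c₁, c₂], high (> c₂), with default
cutpoints (c₁, c₂) = (1.5, 3.0) — i.e. 1–3, 4–6 and 7–10 exposed
intervals; ties at a cutpoint go to the lower category.

Given the active category indicators Z₁(t), Z₂(t), Z₃(t), the event occurs
in interval t with probability

    P(t) = expit(β₀ + β₁Z₁(t) + β₂Z₂(t) + β₃Z₃(t)),

independently across intervals until the first event; subjects without an
event are administratively censored after interval 10. The default
baseline is β₀ = log(0.015) (per-interval probability ≈ 1.48%, ten-year
cumulative incidence ≈ 13.8%); the harness also uses log(5·0.015) and
log(10·0.015) as higher incidence settings. Under the null all group
effects are zero; the default protective alternative is
(β₁, β₂, β₃) = (log 0.8, log 0.65, log 0.5).

A subject whose event precedes W never becomes a user: the realized
exposure trajectory is all-none even though user status was intended.
This is the essential mechanism: surviving subjects drift into ever higher
dose categories, so end-of-follow-up exposure is confounded with survival
itself (guarantee-time / immortal-time bias).

Modeling choices that the problem leaves open, fixed here once:

- **W discrete.** Initiation times are drawn on the interval grid
  {1, …, 10} rather than continuously on (0, 10); a continuous W would be
  discretized by the model immediately anyway.
- **Exposure during the initiation interval.** The subject is considered
  on-drug during interval W itself, so the dose at the event interval
  includes that interval's dose.
- **Event draws.** One uniform per subject-interval over the full horizon,
  taking the first crossing — distributionally identical to sequential
  drawing with early stopping, and convenient to vectorize.

## The three analyses

- **Naive time-fixed Cox**: one row per subject, follow-up time =
  `followup_end`, exposure fixed at the *final* dose category from time 0.
  This is the biased design under study, not a recommended analysis.
- **Time-dependent Cox**: the person-period table is merged into
  (start, stop] counting-process rows wherever consecutive intervals share
  the same category (start = first interval − 1, stop = last interval),
  and the dose group enters as a time-varying covariate. Person-time is
  conserved, and fitting the merged and unmerged rows gives identical
  estimates (asserted in tests).
- **Landmark Cox**: subjects with followup_end ≤ τ are excluded; exposure
  is frozen at the category held during interval τ (the category of the
  cumulative dose accrued through τ), and the clock restarts at τ. Default
  landmark times are 5 and 7. A binary user/non-user coding
  (Z(τ) = I[W ≤ τ]) is available via `landmark_coding="binary"`; the
  three-group coding is the default because the harness reports per-dose
  results.

All designs are fitted by Cox partial likelihood through lifelines
(`CoxPHFitter` for time-fixed designs, `CoxTimeVaryingFitter` for
counting-process rows). Discrete event times make ties heavy, so Efron's
approximation is used throughout; no Breslow option is exposed, as Efron
dominates it in exactly this regime. The Newton solver is run with a much
tighter stopping rule than the lifelines default
(`precision 1e-14`, relative tolerance `1e-16`): on nearly flat partial
likelihoods (few events) the default Newton-decrement rule stops with
coefficients still ~1e-4 away from the maximizer, while the tight setting
agrees with a brute-force maximization of the written-out Efron partial
likelihood to better than 1e-6 at no measurable runtime cost on large
fits. Wald tests are two-sided per coefficient at α = 0.05, with no
multiplicity adjustment.

**Estimability.** A dose group is dropped from a fit — and reported as
non-estimable rather than as a number — when its indicator is constant or
when it contributes no events (a monotone partial likelihood). Its
person-time stays in the risk sets under the reference coefficient. Note
the structural case: with cutpoints (1.5, 3.0) the maximum cumulative dose
attainable by interval 5 is 2.5, so the landmark τ=5 design *cannot*
contain a high-dose group; the harness reports that cell as never
estimable. This is a real feature of landmark analyses — an early
landmark cannot see exposure levels that take longer than τ to reach.

## Landmark conditional densities

`landmark_theory` evaluates, for user-supplied density/survival pairs
(g, G) of the initiation time and (q₀, Q₀), (q₁, Q₁) of the event time
without/with drug use, the residual event-time densities conditional on
landmark exposure status, and checks the null identity: if q₀ = q₁, both
equal q₀(t)/Q₀(τ₀) independently of g. The normalizing integral of the
unexposed density is computed by adaptive quadrature (`scipy.integrate.quad`
with its infinite-interval transformation, absolute tolerance 1e-9);
densities are validated to integrate to 1 within 1e-6. Tests exercise
exponential, Weibull and gamma event-time families with uniform and
exponential initiation-time distributions and τ₀ ∈ {3, 5, 7}.

## Monte-Carlo harness

`run_scenario` replicates the simulate → build designs → fit cycle
(default 1000 replications) and aggregates, per method × dose group:
rejection counts at α, mean estimated HR, bias = mean(ĤR) − HR_true, and
MSE = mean((ĤR − HR_true)²), over the replications where the group was
estimable (exclusions are counted and logged). The true hazard ratio
implied by the logistic DGP is the complementary-log-log equivalent
log(1 − p_g)/log(1 − p₀); under the null it is exactly 1, and for the
rare-event defaults it is within ~1% of exp(β_g). Bias and MSE are
reported signed on the HR scale, so MSE ≥ bias² always holds by the
variance decomposition.

Randomness: each replication r uses the r-th child of
`numpy.random.SeedSequence(root_seed)`; results are bit-identical across
re-runs, and every output directory carries a JSON manifest (config, root
seed, derivation rule, package version) from which `gtbias scenario
--from-manifest` reproduces the CSVs byte-for-byte.

## Problem sizes used by the shipped checks

The test suite runs the full comparison at N = 5000 with 300 replications
(the package's default study size; about 90 s), closed-form incidence
checks at N = 100 000, and estimator-consistency checks at N = 20 000 with
25 replications. The acceptance script runs 1000 replications of the null
scenario with the time-dependent Cox fit (about one minute).

## What the simulation does and does not show

The generator reproduces the *structure* that creates guarantee-time bias
(exposure accrues only with event-free survival) under clean conditions:
administrative censoring only, constant uninterrupted dosing, no
confounding, no competing risks, and a correctly specified
proportional-hazards effect. Passing tests therefore demonstrate the
estimators' behaviour under that mechanism, not robustness to informative
censoring, dose interruptions, or confounding by indication that real
pharmacoepidemiologic data may add on top.

Small-sample caveats at the default N = 5000: only ≈ 250 subjects are
users, so the high-dose group carries only a handful of events. Wald tests
in such cells are conservative-to-erratic, and conditioning on
estimability (≥ 1 event in a ≈ 25-subject landmark group) selects upward-
biased replications — visible as an inflated mean HR for the landmark τ=7
high-dose cell. Method comparisons for sparse high-dose cells stabilize
only at substantially larger cohorts; the qualitative contrast between the
naive and the unbiased analyses is already unmistakable at N = 5000.

## Known limitations

- Stratified/frailty Cox models, covariate adjustment beyond the three
  dose indicators, competing risks and pooled ("super") landmark models
  are out of scope.
- The naive design's biased coding (final category from time 0) is one of
  several biased codings seen in practice; others (e.g. ever-user at
  baseline) share the mechanism but differ in magnitude.
- The landmark high-dose group is structurally empty for τ < c₂/dose + W
  minimum; choose cutpoints and τ jointly when designing a landmark
  analysis.
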