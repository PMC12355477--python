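# Methods

## Model structure

`schizodes` is a patient-level discrete event simulation. Each simulated
patient carries a profile (age, sex, six metabolic markers, smoking,
alcohol, adherence level, prior CHD/stroke/diabetes, antihypertensive
treatment) and a clinical state (stable or relapse, current treatment and
line, consecutive-failure count, active conditions). A pending-event map
holds one absolute time per competing clock; the loop selects the earliest
event, updates the state, and regenerates **only the clocks whose hazards
the event changed** — valid because all stochastic clocks are exponential
and therefore memoryless, so retained clocks keep the correct conditional
distribution. The loop ends at death or at the 10-year horizon.

Events and their multiplicities: relapse, remission and discontinuation
may repeat; tardive dyskinesia, first CHD, first stroke, diabetes and
death occur at most once. Patients enter stable, on the first-line drug,
at t = 0.

### Clocks

| Clock | Law | Hazard |
|---|---|---|
| relapse (stable only) | exponential | −ln(1−p₀) × m, p₀ = untreated annual relapse probability, m = treatment/adherence modifier |
| remission | deterministic | relapse time + episode length (0.5 y) |
| discontinuation | exponential | −ln(1−p_disc), treatment-specific |
| tardive dyskinesia | exponential while on treatment | −ln(1−p_TD) |
| CHD / stroke / diabetes | exponential | −ln(1−risk)/H from the risk equation, H = score horizon |
| death | life-table inverse transform | q′(a,s) = 1 − (1−q)^SMR |

The treatment modifier interpolates the relapse risk ratio towards the
untreated hazard by an adherence weight w ∈ [0,1]: m = RR + w(1−RR), with
w = 0 for full adherence, 0.5 for partial, 1 for none, and w forced to 0
on long-acting injectable routes. The implied multiplier on the fully
adherent hazard, m/RR, is ≥ 1 and equals 1 at full adherence. This
parameterisation was chosen over a bare per-category multiplier because
"non-adherent behaves as untreated" cannot be expressed as a single
multiplier across drugs with different risk ratios.

### Treatment lines and switching

On relapse the consecutive-failure counter increments (by default also for
relapses without a switch; config flag `nonswitch_relapse_counts_as_failure`)
and with probability 0.5 the patient switches: line 1 → the sequence's
second-line drug, and any switch after two accumulated failures → clozapine,
which is absorbing. A patient who had discontinued and relapses without
switching restarts the current-line drug at remission (flag
`restart_treatment_at_remission`). Side-effect-driven switching is
deliberately not modelled; its effect is carried implicitly by all-cause
discontinuation. No drug other than clozapine is ever received twice.

Starting a drug applies its metabolic shifts (removed exactly at
discontinuation, by recomputing marker values from baseline), draws each
short-term side-effect as a Bernoulli on its 3-month incidence (active
0.25 y, with a utility decrement and a one-off management cost), and for
clozapine draws agranulocytosis with an immediate case-fatality check.
Short-term side-effects are charged once per drug, not on restarts.

### Risk equations

`score_risk` evaluates a configured equation per outcome — logistic
(risk = expit(β₀ + Σβx)) or Cox baseline-survival
(risk = 1 − S₀^exp(lp − l̄p)) — over named covariates with optional log
transforms, returning the probability over the score's published horizon
(10 y CHD/stroke, 8 y diabetes in the shipped file). Coefficients live
entirely in config, keyed by a variant label, so a published score can be
swapped in verbatim; the shipped coefficients are authored illustrative
values with conventional signs and plausible magnitudes for a young
first-episode cohort. Diabetes onset sets the diabetes covariate of the
CHD and stroke equations and triggers a rescore; so do treatment start,
discontinuation and CHD (for the stroke equation's prior-CHD term).
Patient age as a covariate is taken at the rescoring time; between events
the hazard is held constant (piecewise-constant hazard), a bounded
approximation at the 10-year desk scale.

Baseline prior CHD/stroke/diabetes act as covariates and suppress the
corresponding first-event clock only; they carry no decrement or chronic
cost at entry (assumed folded into baseline care costs).

## Outcomes

Quality-adjusted time and running costs are exact integrals over the
piecewise-constant state, with continuous discounting
w(t₀,t₁) = ((1+r)^{−t₀} − (1+r)^{−t₁})/ln(1+r) at r = 0.035/y (annual-bucket
discounting would introduce cycle artefacts into a continuous-time model).
Utilities combine additively with a floor at zero; when the floor binds,
the realised loss is attributed to the cardio-metabolic bucket (post-CHD,
post-stroke, diabetes) and the other-side-effect bucket (EPS, weight gain,
sedation, sexual dysfunction, tardive dyskinesia, agranulocytosis) in
proportion to their unfloored contributions, so the decomposition sums to
total QALYs exactly. Relapse costs default to a per-episode lump; a
per-year-in-relapse dialect is available (`relapse_cost_dialect`). Death
truncates accrual and charges a one-off cost; no death disutility beyond
truncation is applied.

Trajectory summaries are computed by a deterministic replay of the
recorded event list (all stochastic outcomes are stored in event
payloads), which keeps the engine and the accounting independently
testable.

## Health-economic layer

First-line results are equal-weight means over the nine sequences sharing
that first line. ICER tables use the lower-QALY arm of each pair as
reference and label dominance instead of reporting signed ratios.
Rankings sort by NMB with ties broken by lower cost then name, across a
£0–£100,000/QALY grid; crossover WTPs are detected and reported.

PSA redraws every uncertain quantity from its stated family (beta for
probabilities, gamma for costs, lognormal for ratios — standard
health-economic convention), re-runs a reduced simulation per draw
(default 200 patients × 20 replications), and reports rank probabilities;
the matrix is doubly stochastic by construction up to floating-point
error. DSA perturbs one parameter at a time to its distribution's central
95% interval when one exists, else ±20%, and reports incremental NMB and
QALY swings in tornado order; parameters without derivable bounds are
skipped with a log entry.

## Random numbers

All streams are `numpy` PCG64 generators keyed by
(master seed, patient, replication, clock). Under common random numbers
(default) the key excludes the treatment sequence, so the baseline cohort
and background death times coincide across compared sequences and shared
clocks stay aligned until pathways diverge — reducing the variance of
pairwise comparisons. A flag switches to fully independent streams per
sequence, reproducing a plain independent-sampling setup. Same master
seed ⇒ byte-identical outputs.

## Synthetic baseline cohort

The cohort generator draws continuous traits from truncated normals at
configured mean/sd within physiological plausibility bounds, and
categorical traits from configured probabilities — i.e. it emulates a
cohort reconstructed from summary-level statistics, not an individual-level
dataset. Markers are independent by default; an optional Gaussian copula
adds dependence with exactly preserved marginals. Real cohorts have
correlated risk factors and heavier tails, so passing tests establish that
the machinery is correct under the stated generative assumptions, not that
the illustrative outputs transfer to any real population.

## Problem sizes and numerical choices

Default study-scale settings are 1000 patients × 100 replications per
sequence and 1000 PSA draws. Tests and the acceptance script run the same
code at desk scale (tens to hundreds of patients; 10⁴–10⁵ trajectories for
oracle and invariant checks), chosen to keep Monte-Carlo error well inside
each stated tolerance. Simultaneous events are broken by a fixed,
configurable priority (death > CHD > stroke > diabetes > relapse >
remission > discontinuation > tardive dyskinesia) so death pre-empts
post-mortem events; ranking ties break by lower cost then name; risks are
clipped to (0, 1) to keep the hazard conversion defined; a 10⁴-event guard
per trajectory surfaces pathological parameter sets; PSA draws violating a
cross-field invariant are resampled with bounded retries.

## Known limitations

- The shipped parameter file is illustrative, not a reproduction of any
  published input set; headline numbers from it characterise the model,
  not the UK evidence base.
- US-derived Framingham-type equations are the only risk-model form
  provided; no UK-recalibrated severe-mental-illness model is included.
- Only first cardio-metabolic events are simulated; no recurrence.
- No dose titration, polypharmacy, partial response, spontaneous treatment
  restart without relapse, or societal-perspective costs.
- Ageing affects hazards only at rescoring events, not continuously.
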