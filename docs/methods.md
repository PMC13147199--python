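# Methods

This note records the model, its conventions, the choices made where
the design was genuinely open, and what the synthetic data do and do
not establish.

## The decision problem

Patients with a recent ischemic stroke from high-grade (70–99%)
intracranial atherosclerotic stenosis face a recurrent-stroke risk of
roughly 14.9% per year on aggressive medical management. PCSK9
inhibitors lower LDL by ~60% on top of statins but cost $600–$10,800
per year depending on drug and payer. The package asks whether adding
a PCSK9i is cost-effective over five years from a US health-care
sector perspective at willingness-to-pay thresholds of $50,000 and
$120,000 per QALY.

Because no trial tests PCSK9i against recurrent stroke in this
population, the treatment effect is synthesised from two links:
(1) the association between attained LDL and recurrence hazard,
estimated by a multivariable Cox model on patient-level data, and
(2) the meta-analytic effect of PCSK9i on LDL, a proportional
reduction of mean 0.60 (SD 0.05).

## Synthetic cohort generator

The generator emulates the marginals of the trial population the
analysis rests on: n = 367; age ~ truncated normal(60, 12.5) years;
baseline LDL log-normal with log-scale median log(91) and σ = 0.354
(median 91, IQR ≈ 72–116 mg/dL); a proportional 30-day LDL reduction
~ truncated normal(0.21, 0.18) on (−0.30, 0.95), applied to baseline so
attained LDL stays positive (median change ≈ −19 mg/dL); binary
covariates (hypertension 89.9%, diabetes 40.6%, smoking 37.6%; male
sex 63.8%) drawn independently of LDL and outcome.

Event times follow a Weibull cumulative hazard `H_i(t) = λ_i t^k`
(default k = 1, i.e. exponential) with

```
log λ_i = log(h0) + β · (log L_i − log L_ref)
```

where `L_i` is attained LDL and `L_ref` the expected log attained LDL
under the defaults. Defaults `h0 = 0.215/yr` and `β = 0.57` were fixed
once so that (a) the event fraction under the trial's follow-up
pattern (uniform administrative censoring over 131–506 days plus a
0.02/yr random-censoring process) is ≈ 16.9%, and (b) the
generator-implied RRR of a 60% reduction — the margins contrast with
the true coefficient — is ≈ 32%, the base case of the decision model.

What the generator does **not** emulate: the joint covariate
distribution of real patients (covariates are independent), covariate
effects on the hazard (only LDL acts; recovery tests are therefore
cleanly identified), time-varying hazards (unless the Weibull shape is
changed), or informative censoring. Passing tests show the pipeline
recovers known structure from data of realistic size and shape — not
that the synthetic patients are exchangeable with trial patients.

## Evidence synthesis

The Cox stage (lifelines `CoxPHFitter`, Efron ties) regresses
`(time_days, event)` on `log(attained LDL)` plus the configurable
covariate set. The exact covariate list and functional form used by
the original analysts are not published; entering attained LDL as its
logarithm is this package's declared interpretation of a benefit that
is "logarithmically dependent" on baseline LDL — a fixed proportional
reduction then shifts every log-hazard by `β·log(1−r)` while the
absolute benefit shrinks at low baseline LDL.

Predictive margins: per patient, annualised rate =
`Λ̂0(365.25 d) · exp(linear predictor)` with the Breslow baseline
cumulative hazard and covariates at observed values; the control side
uses the observed attained LDL, the counterfactual side
`baseline × (1 − r)`. RRR = 1 − mean(treated)/mean(control). The
counterfactual is anchored at *baseline* (pre-statin-effect) LDL; at
r = 0 it therefore undoes the observed reduction and the RRR goes
negative — the no-treatment identity holds for patients whose observed
change is zero. Margins equal a literal per-patient loop to 1e−10
(tested); the bootstrap CI resamples patients with the fit held fixed,
so it reflects cohort-composition uncertainty only, not coefficient
uncertainty.

Pooling both randomisation arms follows a non-significant
LDL-by-arm interaction (Wald test, implemented as
`test_arm_interaction`).

## Decision model

Three health states — stable poststroke, recurrent stroke, dead — with
annual cycles over 5 years. Internally the living states are split by
treatment status (5 computational states) for bookkeeping; the public
trace aggregates the recurrent pair.

Transition probabilities per cycle: stable → recurrent 0.149 (treated:
`1 − 0.851^(1−RRR)` = 0.1039 at RRR 0.32 — the rate-scale convention,
which stays in [0,1] for any RRR < 1; a probability-scale option
multiplies p directly); stable → dead 0.02; recurrent → dead 0.05
(poststroke mortality replaces, not adds to, background mortality);
recurrent is absorbing until death; dead absorbs.

Conventions, each switchable:

- **Cycle accounting (`end`, default).** Each cycle transitions first
  and accrues utilities/state costs on the post-transition occupancy.
  The one-time acute stroke cost attaches to new entries to the
  recurrent state during the cycle. No half-cycle correction.
- **Drug cost basis (`annuity`, default).** The intervention arm is
  charged the full price schedule for the horizon, discounted — a
  committed-therapy (budget-holder) view. The `occupancy` basis
  instead charges only on-treatment occupancy each cycle.
- **Discontinuation (7%/yr; ITT default).** Under the default
  intention-to-treat framing the arm-level treatment effect persists —
  trial-derived effect estimates already average over adherence — and
  discontinuation only moves occupancy between the on/off bookkeeping
  states. Setting `discontinuation_removes_effect=True` reverts
  discontinued patients to the untreated recurrence risk (and, with
  the occupancy cost basis, stops their drug cost).
- **Discounting.** `(1.03)^−(cycle−1)`: year-1 flows undiscounted.
- **Utilities.** Stable 0.9, recurrent 0.5, dead 0 (fixed). A
  parameterisation with `u_recurrent > u_stable` is rejected as
  structurally invalid — otherwise preventing strokes could lower
  QALYs.
- **Ties.** Incremental QALY differences below 1e−12 are treated as
  exact ties (accumulation noise from the on/off split), routing to
  the "undefined ICER" branch rather than dividing by noise.

These conventions were selected because, at the printed base-case
inputs, they reproduce the published deterministic anatomy of the
result — discounted standard-care QALYs ≈ 3.32, intervention ≈ 3.49,
incremental ≈ 0.178, incremental cost ≈ $22.0k at the alirocumab
price — where the plausible alternatives (start-of-cycle accrual,
occupancy-based drug cost, effect-removing discontinuation) do not.

### Stroke-care cost calibration

The acute per-event cost and the annual recurrent-state cost are not
published. Their ratio is set a priori to 1.75:1 (the index admission
dominates US stroke spending); their level is calibrated once so the
probabilistic median 5-year standard-care cost equals the published
≈ $35.9k, giving **$25,900 acute / $14,800 per year**
(`scripts/calibrate_costs.py`, seed 20250101, 20,000 iterations). The
resulting median incremental cost at the alirocumab price ($21.5k)
matches its published counterpart without being targeted — an
out-of-calibration check.

## Probabilistic sensitivity analysis

1000 iterations; per iteration one draw per parameter, shared by both
arms (common random numbers), independent across parameters:

| parameter | distribution | basis |
|---|---|---|
| recurrence probability | beta(mean 0.149, SD 0.008) | stated inter-study SD |
| background / poststroke mortality | beta, SD = 20% of mean | level stated; spread a documented default |
| utilities (stable, recurrent) | beta(0.9, 0.15), beta(0.5, 0.15), method of moments → (2.7, 0.3), (5.06, 5.06) | stated SDs; draws violating the state ordering are redrawn (~5%) |
| price schedule | one gamma multiplier, CV 0.20 | stated price CV; a single multiplier preserves the schedule's shape |
| stroke-care costs | gamma, CV 0.085 each | spread calibrated to the published ±16% interval of the standard-care cost (the published ±23% intervention-arm interval independently confirms the 20% price CV) |
| treatment effect | `LdlMappedRRR`: reduction ~ truncated normal(0.60, 0.05) on (0,1), RRR = 1 − (1−r)^β with β anchored so r = 0.60 gives RRR 0.32 | fast closed form of the margins mapping |

`CoxMappedRRR` additionally draws the Cox coefficient
(β ~ normal(0.57, 0.30), its standard error at n = 367) and is the
full two-link propagation; it roughly triples the RRR spread
(SD ≈ 0.15, bracketing the 20%/50% scenario effects at ±1 SD) and is
available but not default: the evaluation's separate
conservative/optimistic scenarios indicate the synthesis-link
uncertainty was handled by scenario, not sampled in the base PSA.

Cost-effectiveness at threshold λ is `NMB = λ·ΔQALY − ΔCost > 0`
(ties count as not cost-effective); this handles dominance and
negative ΔQALY unambiguously and agrees with `ICER < λ` where both are
defined. Monte Carlo uncertainty of the CE proportion uses the Wilson
score interval (closed form; cross-checked against statsmodels).
Invalid draws are rejected and redrawn with a counter; a redraw rate
above 10% logs a warning.

Because the draw sequence for a given seed does not depend on the
price schedule, re-evaluating at a different price reuses identical
draws. Threshold-price search exploits this: the probability–price
curve is then monotone non-increasing and bisection is well posed
(stop at a $50 bracket or within 0.5 points of the target).

## Numerical notes

- Quantiles everywhere are type-7 (linear interpolation), including
  the IQRs of cohort summaries and PSA tables.
- Transition-matrix rows are constructed with explicit remainders and
  assert row sums of 1 to 1e−15; occupancy traces conserve mass to
  1e−12 and the dead fraction is monotone.
- The engine equals a literal scalar loop re-implementation on random
  parameterisations to 1e−10 (tested over both accounting and both
  cost-basis conventions).
- Seeds: every stochastic entry point takes an integer seed and is
  bit-reproducible; the end-to-end pipeline writes provenance sidecars
  sufficient to re-run each stage.

## Known limitations

- Only recurrent ischemic stroke is modelled; myocardial infarction,
  vascular death and pleiotropic effects are out of scope, so
  cost-effectiveness is, if anything, understated.
- The recurrent state allows no re-stabilisation and no second event;
  the 3-state structure is the minimal one consistent with the stated
  design.
- The exact covariate set and functional form of the original Cox
  model, and the exact distribution families of several PSA inputs,
  are not published; the declared interpretations above are
  configurable defaults, not claims about the original code. The
  residual spread of the published probabilistic results is wider than
  these defaults generate, so probability-scale outputs below the
  distribution's midpoint carry that caveat.
- Federal Supply Schedule prices are not published in the source
  material; the `*_fss` schedules shipped here are placeholders the
  user must replace.
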