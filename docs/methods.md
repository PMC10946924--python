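# Methods

## Model structure

The model is a closed-cohort Markov simulation with four health states —
caries-free, caries, edentulous, dead — and one-year cycles.  Every
single-year age cohort (0–100) by sex enters at its prevalence-based state
mix (edentulous share first, the remainder split caries / caries-free) and
is simulated until the analysis horizon or age 100, whichever comes first;
survivors at the age cap stop accruing events and rewards.  The population
is closed: no births, migration, or quintile mobility.  Expected
occupancies (cohort proportions) are propagated deterministically;
Monte Carlo uncertainty operates over parameters only, never over
individuals.

### Within-cycle event ordering

Competing events inside a cycle are applied in a fixed order: background
death (from every living state), then edentulism onset (from caries-free
and caries), then caries incidence from the caries-free state (scaled by
the intervention multiplier), then treatment-driven recovery back to
caries-free.  The order is a modelling choice — competing-risk ordering is
not identified by annual-probability inputs and shifts results in the third
decimal — and is pinned down by the path-enumeration oracle in the test
suite.  A new case can be treated within its incidence cycle; untreated
cases face the same treated fraction in every later cycle (memoryless
recovery).

### Care seeking

The treated fraction per cycle is `p_toothache + (1 − p_toothache) ×
p_attend`: everyone with toothache is treated, and of the remainder those
who attended a dentist within 12 months are treated.  Only treated episodes
accrue treatment costs; only toothache episodes accrue caries YLD.  Newly
edentulous people who perceive a need for dentures receive a denture
episode; the denture-wearing sub-occupancy incurs replacement episodes at
the annualized probability `1 − 0.41^(1/10)` implied by the 10-year denture
survival of 0.41.

### Half-cycle (within-cycle) correction

Occupancy-based rewards (edentulous person-years, denture-wearer
person-years) use trapezoidal weighting of start- and end-of-cycle
occupancy.  Event flows (incident cases, treatments) are cycle totals and
need no correction; transitions themselves are uncorrected.

## Intervention pathway

A 20% valoric SSB tax reduces consumption by a net 11.52% (SD 9.62
percentage points; own- and cross-price elasticities are folded into this
single input and not re-estimated).  Consumption is the quintile's
population-mean daily cups (consumers and non-consumers; the consumer share
is carried for reporting only, so it is never multiplied in twice).  Sugar
intake is cups × grams-per-cup; the default 26 g/cup scales a 39 g free
sugar content per 375 mL serve to a 250 mL cup, and is configurable because
the survey-derived value is not published.  The sugar reduction maps to an
incidence multiplier via the linear dose slope of 0.010 ΔDMFT per 10 g
sugar/day, equating the fractional annual DMFT change with a fractional
incidence reduction.  That equivalence is dimensionally loose but is
adopted deliberately as the field's convention for this intervention class;
severity (1.64 teeth/case) is applied only when counting decayed teeth,
never inside the incidence effect.  The multiplier applies identically to
deciduous and permanent dentition, is clamped at zero (unreachable for any
printed central value), equals 1 below age 2 (no consumption data), and is
scaled by a constant per-cycle retained-effectiveness fraction δ (not
compounded year-on-year) that the threshold analysis searches over.

## Outcomes and costs

DALYs are YLD-only: dental disease is nonfatal here, so no years-of-life
lost are accrued and mortality is background-only.  Symptomatic episodes
carry disability weight 0.010 over 28 days (ages < 17) or 55 days (17+),
one flat product per episode — the two-phase toothache description behind
those durations has no published phase-specific weights, so no finer
decomposition is attempted.  Edentulism carries weight 0.067 per
person-year.

Healthcare costs per treated caries episode are one check-up (AUD$54.69)
plus the restoration fee (AUD$189.61) per decayed tooth at the episode's
sampled severity; the per-tooth multiplication is a documented choice (a
per-episode mode is a one-line change in `episode_costs`).  The printed
fees are treated as already blending the 85%/15% private/public mix.
Denture provision costs AUD$2,798.08 per pair over three visits with 60
minutes of total chair time (the "three appointments totaling 60 min"
reading; per-visit travel is still charged three times, and both the visit
count and minutes are parameters for the other reading).  The societal
perspective adds AUD$20.71 travel per visit and AUD$49.22/h for travel (60
min return) and chair time, charged identically for children (a guardian's
time).  Intervention (tax administration) costs — AUD$5.8M year 1, AUD$4.47M
thereafter — enter both perspectives, in the intervention arm only, pro-rata
by population share for quintile-level runs.  Year 1 is undiscounted; year
t ≥ 2 is discounted by (1.03)^−(t−1).  All amounts are 2020 AUD; no
re-inflation logic exists.

## Probabilistic sensitivity analysis

2000 draws by default.  Families are not dictated by the source material
and follow standard CEA practice, moment-matched to the printed mean/SD:
gamma for costs and the severity count; beta for disability weights,
denture survival, and other probabilities; normal truncated at zero
(rejection-sampled) for the two effect sizes.  Truncation raises the
realized mean of the heavily-uncertain sugar-dose slope above its central
value — visible as PSA mean benefits exceeding the deterministic run — which
is the known, accepted cost of forbidding negative effects.  With every SD
at zero each draw reproduces the deterministic run bit-for-bit.  Draw *i*
under seed *s* derives from `SeedSequence(s, spawn_key=(i,))`, so streams
are reproducible across platforms and independent of batch size.  Both arms
of a draw share one parameter realization (common random numbers), so
increments isolate the intervention effect.

Cost-effectiveness is uniformly NMB = 50,000 × ΔDALY + societal savings
> 0, which counts dominant draws and draws with ICER below the threshold
under one rule.  Uncertainty intervals are 2.5/97.5 percentiles across
draws.  The threshold analysis bisects δ ∈ [0, 1] to 1e-3 with a fixed draw
stream across evaluations; the default criterion is probability of positive
NMB ≥ 0.5, with mean-NMB ≥ 0 available (`criterion="nmb"`), since the
published analysis does not state which was used.

## Synthetic inputs

The original epidemiology inputs are unpublished, so the generator supplies
internally consistent stand-ins.  Fixture mode (deterministic, no RNG path)
reproduces the printed consumption rows exactly — cups/day 1.41, 1.18,
0.94, 1.02, 0.72 by quintile (note quintiles 3 and 4 are not monotone) with
consumer shares 44.7–29.0% — and pairs them with smooth age curves chosen
to be shape-realistic at national scale: caries incidence unimodal, peaking
at 0.35/yr around age 12 with an adult floor of 0.08 (implying roughly 0.19
cases/person/yr population-wide, the order implied by published accrual
totals); edentulism incidence zero before age 40 rising logistically to
2%/yr; entry edentulism prevalence rising to ~25% in extreme old age;
Gompertz mortality (slope 0.09, modal age 88) plus an infant spike; care
seeking of 15% toothache, ~55–65% annual attendance, 30% perceived denture
need — plausible Australian magnitudes chosen once, not calibrated.  Entry
caries prevalence is the steady state h/(h + r) implied by incidence and
recovery.  The deciduous-dentition share (1 through age 5, linear to 0
across ages 6–14) is carried as data for audit; it does not enter the
effect pathway because the dose slope applies to both dentitions.
Single-age SSB exposure is constant within the source's age bands, and one
quintile-level mean is used at all ages ≥ 2.

Synthetic mode perturbs curve scales, the incidence peak, and the (strictly
decreasing) consumption gradient under a seed, for property tests.

What passing tests therefore show: the machinery — transition algebra,
accounting identities, discounting, PSA plumbing, equity and threshold
logic — is correct, and the qualitative published findings (dominance, a
consumption-driven equity gradient, decade-scale savings) emerge from
printed scalars plus shape-realistic epidemiology.  What they do not show:
agreement with the published point estimates, which depend on unpublished
age-specific inputs.  In particular, quintiles here differ only in
consumption, so the Q1/Q5 benefit ratio tracks the cups ratio (~2.0); the
published ~3-fold gradient also reflects quintile-specific epidemiology the
generator does not emulate.

## Numerical notes

* Occupancy conservation is enforced at 1e-8 per transition (internal
  error, not a warning); the kernel matches exact path enumeration to
  1e-12 on small instances.
* Edentulous occupancy is monotone as a share of the living, not in
  absolute terms (background death drains it); tests assert the share.
* Multi-year → annual probabilities always use `1 − (1 − p)^(1/n)`, never
  division.
* Problem sizes: 202 cohorts × ≤100 cycles × 2000 draws runs vectorized
  (draws as a broadcast axis) in seconds; the acceptance script uses 2000
  draws for the CEA and 1000 for each threshold bisection, and
  deterministic central-value runs for the per-quintile equity gradient.

## Limitations

Beyond the synthetic-input caveat: no severe-tooth-loss sequela, no
substitution to untaxed drinks, no population growth, no tax-revenue or
budget-impact accounting, no out-of-pocket disaggregation, and no
downstream treatment pathways (root canals, extractions, general
anaesthesia) — all exclusions shared with the analysis this package
re-implements.
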