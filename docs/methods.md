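# Methods

## The decision problem

`drscreen` models population screening for diabetic retinopathy (DR) among
patients with diabetes mellitus in two Chinese settings (rural and urban),
comparing three strategies — no screening, community fundus-photography
screening, and telemedicine (store-and-forward teleophthalmology)
screening — on discounted lifetime costs (2020 USD, societal perspective)
and quality-adjusted life years (QALYs).  Strategies are compared by the
incremental cost-utility ratio ICUR = ΔC/ΔQ against the WHO-convention
willingness-to-pay thresholds of 1× and 3× per-capita GDP per QALY
($7,000/$21,000 rural, $12,000/$36,000 urban; the thresholds are taken as
given constants, not derived from GDP decompositions).

## Cohort model

A unit cohort starts at age 50, not previously screened, and is followed
for 30 annual cycles.  Health states are NO_DR, NPDR, PDR, DME, SVI
(severe visual impairment, bilateral BCVA < 6/60), and DEATH, with
forward-only progression (NO_DR→{NPDR, PDR}, NPDR→{PDR, DME}, PDR→{DME,
SVI}, DME→SVI, any→DEATH); recovery is not modelled.  Because detection
changes both costs and progression rates, the engine works on the product
of health state and management flag: undiagnosed, NPDR under annual
follow-up observation, treated PDR (photocoagulation), treated DME
(anti-VEGF).  SVI is split into first-year and established sub-states so
the larger first-year cost can be charged exactly once.  The expanded
space has ten states; DEATH is absorbing.

Within a cycle the order of operations is: (1) any scheduled screening
round (flags and event costs change; health states do not); (2) mortality;
(3) disease progression among survivors (competing-risk convention; the
evidence base is silent on ordering, and mortality-first is the standard
cohort-model choice).  Patients under follow-up observation whose disease
progresses are detected and treated at once (clinical surveillance, not
re-screening); by default treated PDR cannot progress to DME
(`options.treated_pdr_to_dme` restores that path), reflecting the
treated-state description "remain or progress to severe visual
impairment".

Mortality is an age-specific background schedule q(age) multiplied by a
diabetes risk ratio of 1.97, replaced by 3.9 for SVI patients
(`mortality.svi_multiplier_mode: multiply` stacks the two instead — the
evidence lists the multipliers in parallel without saying whether they
compose), capped at 1.  No background schedule is published for this
cohort, so the default is a synthetic Gompertz law q(age) = min(1, a·e^{b(age−50)})
with a = 0.004, b = 0.085 — about 0.4% annual mortality at 50 doubling
every ~8 years, a plausible adult shape; any real life table can be
supplied via config (`kind: table` or `kind: file`).  Ages beyond the
schedule reuse its last entry.

Utilities (QALY weights) attach to health states only (0.95 / 0.79 / 0.70 /
0.70 / 0.55; death 0); treated and untreated states share the same weight.
Costs and utilities are discounted at 3.5% per year.  Half-cycle
correction is implemented as the trapezoidal average of cycle-start and
cycle-end occupancy, applied to utilities and recurring costs (annual
follow-up observation $122.32; established-SVI years $3,600).  One-off
amounts — screening, hospital examination, treatment initiation ($137.60
photocoagulation, $1,741.46 anti-VEGF), and the first SVI year ($8,800) —
are charged undampened at the cycle they occur; cycle-start events are
discounted by (1+r)^{-c} and within-cycle flows by (1+r)^{-(c+1)}.

## Screening cascade

A screening round reaches the undiagnosed, not-yet-impaired states.
Uptake (probability of attending) and referral acceptance (probability a
called-positive attendee goes to hospital) default to 0.80 and 0.70 for
both modalities and settings.  **These are synthetic assumptions**, marked
as such in the fixtures: no compliance values are published for these
programmes, and results that hinge on modality differences in compliance
cannot be reproduced under this default (see Limitations).

Test behaviour is parameterized by grade-call misclassification (normal
called NPDR, NPDR called normal, PDR called NPDR/normal) plus a separate
DME sensitivity/specificity pair.  A referral is triggered by a
grade-positive call for true NO_DR/NPDR/PDR and by a positive DME call for
true DME.  By default a false-positive DME call in a non-DME state does
*not* trigger referral: with the community DME specificity of 0.79, the
strict layered rule would refer ~25% of healthy attendees every round,
whose examination costs alone exceed any published incremental cost for
these programmes; the strict rule is available as
`options.dme_false_positive_referrals`.  Hospital confirmation (full
ophthalmologic examination, $100 including transport) is assumed perfect:
confirmed NPDR enters follow-up observation, confirmed PDR/DME starts
treatment, false positives pay the examination only, false negatives stay
undiagnosed until a later round (no symptomatic presentation channel).
Attendance is independent across rounds.  Schedules are one-off (first
cycle only) or every k ∈ {1..5} years starting at cycle 0.

## Costing

Programme costs are built from itemized tables.  Capital items (camera,
chart, laptop; telemedicine software and installation) are annualized by
the annuity factor ((1+r)^n − 1)/(r(1+r)^n) with r = 3.5% and a 5-year
life, no salvage value.  The published two-decimal convention *truncates*
the factor 4.51505… to 4.51 (ordinary rounding gives 4.52, which is
inconsistent with the published annualized amounts such as 24,000/4.51 =
5,321.51); `rounding="published"` reproduces that convention and
`rounding="exact"` uses full precision.  Dividing annual programme cost by
20,000 persons screened per year gives $2.44 (community) and $1.84
(telemedicine) per attendee.  Yuan-denominated inputs convert at 6.9762
CNY/USD.  The rate/probability conversion r = −ln(1−p)/t is provided for
config entries flagged as multi-year cumulative incidence.

## Sensitivity analysis

One-way analysis moves each uncertain parameter to base×(1∓f) — f = 10%
for probabilities, utilities, test accuracy, and the mortality
multipliers; 20% for programme and examination costs; 50% for treatment
and SVI costs (the published per-parameter split is not available; the
assignment is a config field `costs.uncertainty_fraction`) — clipped to
the parameter's support, with joint invariants repaired by clipping
(treated progression capped at untreated; complement rows recomputed)
rather than aborting.  The tornado orders parameters by the absolute ICUR
swing.

Probabilistic analysis fits method-of-moments distributions from each
parameter's 95% interval (σ = (hi−lo)/3.92): beta for prevalence,
transitions, utilities, test accuracy, and compliance; gamma for costs;
degenerate intervals are point masses.  "Normal called normal" is the
complement of "normal called NPDR" and is recomputed, not drawn.  Draws
are independent (no published correlation structure); a draw violating a
structural invariant — most often treated-PDR progression exceeding the
untreated rate, whose intervals overlap — is rejected and redrawn (~16%
of iterations; the count is reported).  Checks that only the transcribed
point estimates must satisfy (utility severity ordering, since PDR and DME
share one distribution; agreement of the examination total with its line
items; base-within-own-CI) are excluded from draw validation — enforcing
them would truncate every distribution to its interval.  Per draw all
strategies are rerun; ICUR uncertainty is summarized by percentile (2.5/
97.5) intervals over defined-ICUR draws, and cost-effectiveness
acceptability curves report the fraction of draws with positive net
monetary benefit λ·ΔQ − ΔC over a λ grid.  The default 1,000 iterations
(unpublished in the source analysis) reruns in seconds; results are
bit-reproducible given a seed.

## Microsimulation oracle

`synthetic_data.microsimulate` simulates individual trajectories with the
same event ordering, valuation vectors, half-cycle convention, and
discounting as the cohort engine, but re-derives every transition from the
raw annual probabilities by per-individual draws (death first, then
progression) — it shares no state-propagation code with the engine, so
agreement of the two (within 3 Monte-Carlo standard errors at 10⁵
individuals, across both modalities and interval schedules) is a genuine
check of the transition algebra.  The generator also produces lognormally
perturbed, invariant-repaired parameter sets for property tests.

## Interval recommendation

Walking from the longest interval (one-off counts as longest) to the
shortest, a shortening is accepted when it dominates the last accepted
option or its pairwise ICUR against it falls below the 3×-GDP threshold;
the shortest accepted interval is recommended.

## Numerical choices

QALY differences below 1e−9 are treated as zero to guard the ratio;
transition-matrix rows are verified row-stochastic to 1e−12 and cohort
mass is conserved to 1e−12 per cycle; the annuity factor uses the
expm1/log1p form, stable as r → 0 where it approaches n.  Acceptance-scale
problem sizes are 10⁵ individuals for the oracle and 10³ PSA iterations.

## Limitations — what the passing tests do and do not show

* The synthetic life table and compliance values have the right *shape*
  but are not Chinese data; absolute cost and QALY levels therefore differ
  from the published base case (our no-screening arm accrues far more SVI
  cost than the published $214 per person implies — that figure is not
  reconstructible from the published SVI cost stream and prevalence under
  any life table we examined).  In this parameterization screening is
  cost-saving (dominant) rather than merely cost-effective.
* Under equal compliance the community test detects more disease than
  telemedicine in every channel (NPDR referral 0.78 vs 0.58, DME
  sensitivity 0.82 vs 0.80, PDR 0.98 both), so telemedicine ends up
  cheaper but with slightly fewer QALYs.  The published finding that
  telemedicine gains *more* QALYs therefore requires modality-specific
  compliance, which is unpublished; the acceptance checks asserting that
  ordering, the published tornado ranking (our tornado is topped by the
  ±50% SVI-cost bands instead of the treated-PDR progression), and the
  urban PSA majority are left failing by design rather than tuned to pass.
* DME care is idealized (single state, one treatment initiation, no
  recurrence); no symptomatic-presentation channel for false negatives; no
  capacity constraints or repeat-attendance correlation; treated states
  are absorbing with respect to treatment.
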