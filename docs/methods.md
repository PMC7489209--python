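# Methods

## Model structure

`gcscreen` is a discrete-time (annual-cycle) individual-level state-transition
model.  Each simulated person enters at age 20 in normal mucosa and is
followed to death or age 100.  The within-year event order is:

1. smoking-status update (never → current by an age/sex/year initiation
   probability; current → former by a net cessation probability; former
   smokers never re-initiate),
2. other-cause death (period life table by age, sex and calendar year,
   where calendar year = birth year + age),
3. screening, if due under the strategy (including post-ESD surveillance
   endoscopy),
4. natural-history transition (at most one forward step per year) and,
   for diagnosed individuals, the annual gastric-cancer death draw,
5. cost and QALY accrual for the year.

Events in cycle *k* (age 20 + *k*) are discounted by (1 + r)^−k with
r = 3% for both costs and effects; the year of death accrues no QALY, and
a year of gastric-cancer death accrues the terminal-care cost in place of
the phase cost.  No half-cycle correction is applied: with individual-level
annual cycles over an 80-year horizon the correction is second-order
relative to Monte-Carlo noise.

### Disease states and risk modification

The cascade is forward-only: normal → atrophic gastritis (AG) → intestinal
metaplasia (IM) → dysplasia → preclinical local → preclinical regional →
preclinical distant; each preclinical stage competes annually between
symptomatic surfacing (to the same-stage clinical state; the symptom draw
is evaluated before the progression draw) and stage progression.  Lesion
regression is not modelled.  The *H. pylori* relative risk multiplies the
normal→AG and AG→IM edges; smoking multiplies those plus IM→dysplasia.
This placement follows the etiologic ordering of the cascade —
infection-driven inflammation initiates the precancerous field, smoking
also accelerates later precancerous change — and is configurable.
Products are clipped to probability 1.  *H. pylori* status is fixed at
entry (no acquisition, clearance or eradication therapy during follow-up);
the modelled histology is non-cardia intestinal-type adenocarcinoma only.

### Screening and treatment

A strategy is (start age, stop age, interval); "no stopping age" means
screening to the model horizon (age 100).  Adherence is perfect by default
(a configurable knob exists).  Endoscopy is positive with probability
0.886 (sensitivity) in lesion states — dysplasia or preclinical cancer —
and 0.149 (1 − specificity) otherwise; false positives incur no cost or
state change beyond the endoscopy itself, since biopsy is part of the
procedure and no separate work-up is priced.  Procedural complication
(1.95 × 10⁻⁵) and death (1.1 × 10⁻⁶) are drawn independently of the result.

Screen-positive dysplasia undergoes ESD (complete resection 0.90,
complication 0.0242, death 1.6 × 10⁻⁴).  Complete resection returns the
mucosa to intestinal metaplasia and schedules 5 yearly surveillance
endoscopies during which the lesion recurs at 0.014/yr; a recurrence
surfacing in a surveillance year can be found by that year's endoscopy and
re-treated.  Incomplete resection is referred to immediate gastrectomy
(complication 0.0615, death 0.0044, recurrence 0.004/yr) — the source
tables are silent on this path, and immediate completion surgery matches
clinical practice while keeping all detected dysplasia treated.

Screen-detected preclinical cancer is diagnosed at its current stage and
enters the same stage-specific survival model as symptomatically detected
cancer: earlier-stage detection (stage shift) is the entire survival
benefit mechanism.  Screen-detected local cancer is treated by gastrectomy
by default (`local_cancer_surgery=False` switches the procedure off);
regional and distant disease receive stage-specific care whose cost is
carried entirely by the stage treatment-phase costs.  Gastrectomy has no
separate direct price in the cost table — its direct cost is considered
part of the first-year stage cost — so the surgery event contributes
patient-time hours (136 h), complication management and its utility
decrement only.  Cancer recurrence after treatment is implicit in the
stage-specific survival curves; the explicit recurrence probabilities
apply only to the resected-dysplasia surveillance pathway.

Deaths caused by procedures (endoscopy, ESD, surgery) are counted as
non-cancer deaths.

### Economics

Costs are 2015 US$ from the societal perspective: direct medical costs plus
patient time valued at $16.75/h.  Stage treatment phases: first-year cost
at diagnosis (351 h), subsequent-year cost thereafter (48 h), and a
terminal-care year ($51,497, 512 h) replacing both in the year of
gastric-cancer death.  A person dying of other causes accrues nothing in
the death year.  The two published complication-management prices ($380
and $852) are applied as an equal-probability minor/major split.

Utilities: 1.0 until cancer diagnosis, then the stage utility (local
0.773, regional 0.590, distant 0.404) from diagnosis until death —
survivors do not return to 1.0, a deliberately conservative reading that
is configurable.  Procedure time losses (endoscopy 1 day, complicated
endoscopy 1 week, surgery 2 weeks, complicated surgery 1 month) are
modelled as time at utility zero, i.e. subtracted from the year valued at
the current state utility; only endoscopy/surgery decrements are
published, and ESD uses the surgery pair as the closer clinical analogue.

### CEA

Outcomes are aggregated per 1000 individuals entering the model; deaths
and endoscopy counts undiscounted, QALYs and costs discounted.  QALY gains
are computed against the no-screening arm simulated on the same population
with the same natural-history random streams (common random numbers): the
engine draws a fixed block of five uniforms per person-year from the
natural-history stream regardless of state or strategy, so trajectories
are bit-identical across arms except where screening intervened, and
screening consumes a separate stream.  Strong dominance is applied first,
then extended dominance iteratively until frontier ICERs strictly increase
(a collinear middle point — equal successive ICERs — is pruned, since it
adds nothing at the same price per QALY).  Equal-cost ties rank by
descending QALY, the worse duplicate being marked strongly dominated.

## Calibration

The nine transition probabilities (six progression, three symptom) are
calibrated by uniform independent random search within per-parameter
bounds (Latin-hypercube sampling available via `method="lhs"`); each
candidate simulates the no-screening scenario — the targets predate any
screening program — with one fixed seed shared by all candidates, so score
differences reflect parameters, not noise.  The score is a weighted sum of
squares over age/sex incidence cells (rates per 100,000 person-years,
5-year age bins) and stage-distribution cells (percentage points), with
unit weights on both so the components share a rough scale; an empty model
stratum facing a nonzero target contributes the full squared target.  The
best *k* = 50 sets form the reported min–max uncertainty envelope.

## Sensitivity analysis

One-way analysis reruns the 50-75-3 vs no-screening comparison with a
single parameter at each end of its range (published 95% bounds where
available, ±20% otherwise, and the discount-rate scenario variants).  The
probabilistic analysis fits beta (probabilities) and gamma (costs)
distributions by method of moments — mean at the base value, SD = range /
(2 × 1.96), reading the one-way range as a 95% interval; parameters with a
distribution family but no published range use the ±20% convention.  Each
of the (default 1000, desk-scale 200) draws samples all uncertain inputs
independently, reruns both arms with common random numbers and one fixed
simulation seed across draws, and records the per-1000 incremental cost
and QALYs; CEAC(λ) is the fraction of draws with λ·ΔE − ΔC ≥ 0.
Natural-history parameters stay at their selected calibrated set during
the PSA.

## Synthetic inputs

The generator emulates the statistical shape, not the values, of the
unpublished inputs:

- *H. pylori* prevalence: logistic decline across birth years 1908–2003
  between plateaus 0.85 and 0.10, midpoint 1955, slope 0.10/yr — roughly
  30% → 14% over the simulated 1965–1985 birth cohorts, consistent with
  the well-documented secular decline in Japan.
- Life tables: Gompertz–Makeham q(a) = 2.5 × 10⁻⁴ + A·e^(0.095a) with
  A = 2.5 × 10⁻⁵ (men) and 1.3 × 10⁻⁵ (women), flat in calendar year;
  this yields life expectancy near the Japanese range and a strictly
  decreasing survivorship curve.
- Smoking: initiation concentrated at ages 20–39 (men 3.5%/yr then
  1.5%/yr; women about a third of that), net cessation 3%/yr before 50 and
  6%/yr after, producing adult current-smoking prevalence of the right
  order for these cohorts.
- Post-diagnosis hazards decline over follow-up years 1–6 and are
  stage-ordered year by year (e.g. first-year 0.03 / 0.22 / 0.55 for
  local/regional/distant in men; women × 0.9), giving 5-year survival
  near 0.91 / 0.52 / 0.04.
- Ground-truth transitions (p_normal_ag = 0.004, p_ag_im = 0.03,
  p_im_dys = 0.006, p_dys_local = 0.04, p_local_regional = 0.30,
  p_regional_distant = 0.40; symptom probabilities 0.18 / 0.40 / 0.75;
  RR 4.0 for *H. pylori*, 2.0 / 1.4 for current/former smoking) were
  chosen once so that the no-screening arm yields lifetime gastric-cancer
  mortality of order 10 per 1000 and a local/regional/distant diagnosis
  split near 47/34/19 — magnitudes a Japanese pre-screening cohort would
  plausibly show.  Default calibration bounds are (0.5×, 2×) truth.

What the generator does **not** reproduce: actual registry incidence or
survival, real life tables or smoking surveys, calendar-year trends in any
schedule, *H. pylori* eradication, or non-1965–1985 birth cohorts.
Passing tests therefore demonstrate that the machinery is correct — state
accounting, common-random-number equivalences, dominance logic, parameter
recovery — not that the synthetic world quantitatively matches Japan.

## Numerical choices and scale

Simulations are vectorised across individuals per model year (about 1 s
per 10⁵ lifetimes), which sets the desk-scale defaults: 10⁵ individuals
for strategy comparisons, 300 × 20,000 for the calibration recovery
experiment, 200 × 10⁴ for the PSA.  Full policy-evaluation scale (10⁷
individuals, 6000 searches × 10⁶, 1000 draws) is reached through the same
arguments; nothing else changes.  All
randomness flows from one `SeedSequence` root: a population child stream,
a natural-history stream and a screening stream per run.  Monte-Carlo
checks in the test suite use 3-standard-error bands; two-sample
indistinguishability checks use α = 0.01.

## Known limitations

- The published no-screening arm includes ~0.8 diagnostic endoscopies per
  person (symptomatic work-up); `gcscreen` counts screening and
  surveillance endoscopies only, so its no-screening endoscopy count is 0.
- Clinical (symptomatically diagnosed) cancer carries no discrete
  procedure event; all its treatment cost and disutility is phase-based.
- Stage utilities apply from diagnosis to death; long-term survivors never
  recover utility 1.0.
- Calibration assumes the targets were produced under no screening; it
  does not model the partial screening exposure a real 2006–2008 registry
  population would have had.
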