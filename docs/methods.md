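# Methods

This note documents the model implemented in `cessation_cea`: its
structure, parameter conventions, numerical choices, the synthetic data it
runs on by default, and the limits of what its tests demonstrate.

## Decision problem and cohort

Two smoking-cessation strategies are compared for a closed cohort of
65-year-old current smokers with cancer, from a single healthcare payer's
perspective, in 2015 Canadian dollars: a basic program (screening, advice,
referral; $16 one-time administration; 12-month abstinence 0.04) and a
best-practice program (basic plus varenicline $150, twelve 15-minute
nurse-counseling sessions $105, administration $47; 12-month abstinence
0.24). Both arms share a background self-quit probability (0.015/year) and
duration-dependent relapse. Outcomes are discounted cost, quality-adjusted
life-years and life-years; strategies are compared by ICER and by net
monetary benefit.

## State space and transitions

The Markov model has three conceptual states — current smoker, former
smoker, dead — with the former-smoker state expanded into one-year tunnel
compartments (13 expanded states in all) because the annual relapse
probability depends on time since quitting (bands 1–2, 3–4, 5–8, 9–10,
10+ years with dwell times 2, 2, 4, 2, ∞). Cycle length is one year;
the horizon is age 100 (35 cycles), where the utility age-bands end;
survivors past 100 accrue nothing further. The synthetic life table is
closed with q(110)=1 so extended horizons still absorb the cohort.

Within a cycle, events are ordered deterministically: death first (annual
probability by age and smoking status), then quitting or relapse among
survivors. Any fixed order conserves probability; this one is stated so
tests are exactly reproducible. The quit schedule is: cycle 1, the arm's
12-month program abstinence; cycle 2, a residual program-driven quit
probability (0.02) in the best-practice arm only (a flag applies it to
both arms); later cycles, self-quit. Relapsers return to the smoker state
and are eligible only for self-quit thereafter — program effects and
program costs are one-time. Death is a single absorbing state; splitting
it by cause would not change any payoff.

## Mortality derivation

Annual death probabilities by age, sex and smoking status come from a
six-step construction on the hazard scale:

1. take q(age) from a sex-specific life table;
2. take f(age), the fraction of deaths at that age due to cancer;
3. convert to hazards: m = −ln(1−q), m_cancer = m·f, m_noncancer = m·(1−f);
4. scale the cancer component by an excess multiplier k ≥ 1 (default 2.0)
   to move it from general-population to cancer-patient level;
5. apply the smoking-status hazard ratio (current 1.50, former 1.30,
   versus never smokers) to the **non-cancer** component;
6. convert back: p(age, status) = 1 − exp(−[HR·m_noncancer + k·m_cancer]).

Two conventions deserve note. First, hazard ratios act on the hazard, not
the probability, which keeps p ≤ 1 and matches standard HR semantics; for
small hazards p ≈ HR·m to first order (a tested property). Second, the HR
is restricted to the non-cancer component (`hr_on="noncancer"`;
`"total"` is available). The alternative — multiplying the whole
cancer-patient hazard — makes the survival gap between current and former
smokers implausibly large once the hazard carries a realistic cancer
load, and produces lifetime incremental life-years several times larger
than the incremental QALYs would support; with the non-cancer convention
the basic-arm totals land directly on the expected scale (≈$296k,
11.6 discounted LY for males). The general-population life table serves
as the never-smoker baseline (no smoking-prevalence deconvolution, for
which there are no inputs), and mortality depends on age but not on time
since diagnosis.

At q=1 (the closed terminal age) the hazard would be infinite; it is
capped at 50 and a warning is raised only if this happens before the
terminal age.

## Payoffs and discounting

Per cycle, accrued on the post-transition occupancy (optionally on the
start/end average when the half-cycle correction flag is set; default
off):

* **cost** — annual cancer care ($25,058) for the alive fraction (a
  scenario flag excludes it); the smoking-attributable annual cost ($403)
  for current smokers **and for former smokers in their first four years
  of abstinence** (`smoking_cost_decay_years`, default 4; 0 drops it at
  the quit date); and the one-time program cost in cycle 1.
* **QALY** — occupancy times (sex/age-band/status utility − 0.12 cancer
  decrement). Utilities are EQ-5D population values on two age bands
  (65–74, 75–100); former-smoker utility exceeds current-smoker utility
  within every band.
* **LY** — the alive fraction.

Cycle-t payoffs are discounted by (1+r)^−t at r = 5%/year. The one-time
program cost is charged undiscounted at entry (t=0) in both the
discounted and undiscounted ledgers; this is stated explicitly because
cycle-timing conventions are a common source of irreproducibility.

The smoking-cost decay window reflects that excess smoking-related
hospital and physician utilization declines over several years of
abstinence rather than vanishing at the quit date; four years matches the
first two relapse bands, after which relapse risk (and, by assumption,
smoker-level utilization) drops an order of magnitude. It also makes the
model's scenario behavior coherent: with an immediate drop, lifetime
smoking-cost savings would exceed the $286 program-cost difference and
the best-practice arm would become cost-saving the moment cancer-care
costs are excluded — contradicting the intended "more costly, more
effective" structure of both the base case and the cost-exclusion
scenario.

## Incremental analysis

`compute_icer` classifies dominance before reporting any ratio (dominant:
cheaper and at least as effective; dominated: the reverse), reports
ICERs only for genuine trade-offs, never divides by a zero effect
difference, and keeps unrounded ratios internally while reporting to the
nearest dollar. Cost-effectiveness at a threshold λ is decided by the
sign of NMB = λ·ΔQALY − ΔCost rather than by comparing an ICER to λ, so
cost-saving (southeast-quadrant) draws are handled cleanly.

## Sensitivity analysis

**Distributions.** Each uncertain parameter carries a base value and a
95% interval, converted to SE = (upper−lower)/(2·1.96). Costs are gamma
(shape = base²/SE², scale = SE²/base; mean = base), probabilities and the
cancer utility decrement beta (matched to mean = base and variance = SE²,
falling back to a fixed value with a warning if the variance is
infeasible), hazard ratios lognormal with μ = ln(base) and
σ = (ln upper − ln lower)/(2·1.96) — the base value is the **median**,
the standard convention for a ratio reported with a CI. The state
utilities have no published ranges and are fixed in the PSA; the time
horizon is a scenario, not a sampled quantity.

**Tornado.** Each parameter in turn is set to its lower and upper bound
(all else at base) and the full male base case is re-run; entries are
ranked by the absolute ICER swing. Endpoints where the effect difference
is not positive are flagged with the dominance label instead of a number
(the former-smoker HR at its upper bound, 1.81 > 1.50, flips the survival
comparison). The time-horizon entry truncates the run to 2 and 4 cycles.

**PSA.** Per draw, every non-fixed parameter is sampled through its
inverse CDF, mortality is re-derived, both arms re-run, and (ΔC, ΔQALY)
recorded; the CEAC is the fraction of draws with non-negative NMB over a
willingness-to-pay grid. Sampling is independent across parameters by
default (no correlation structure is specified by the sources). Because
the former-smoker HR has the wider CI, independent sampling occasionally
draws hr_former > hr_current; an optional rank-coupling flag samples both
HRs from one shared quantile, preserving their marginals while keeping
their order — this is the configuration used for the headline
acceptability figure. Draws violating a model invariant would be rejected
and redrawn (counted and logged; with the packaged ranges none occur).
All randomness flows from one `numpy` Generator seeded explicitly, so
results are bit-reproducible given the seed.

## Synthetic inputs

The default inputs emulate the structure, not the values, of national
statistics: a Gompertz life table q(age) = 1 − exp(−a·e^{b·age}) on ages
65–110 with optional seeded lognormal hazard noise (monotonicity restored
by cumulative max), and a cause-of-death split declining linearly from
f(65) to f(110).

Defaults (chosen once, as calibration conveniences rather than claims
about any real population): b = 0.12 for both sexes; a = 1.89·10⁻⁶ for
males and 1.57·10⁻⁶ for females, giving life expectancies at 65 of 23.5
and 24.9 years; cancer share of deaths 0.60 (male) / 0.64 (female) at 65
declining to 0.10 at 110 — at 65, cancer accounts for a larger share of
female deaths because circulatory mortality rises later for women;
excess cancer multiplier 2.0. Under these defaults the male basic arm
accrues ≈ $295.8k, 7.21 QALY, 11.62 discounted LY — the scale a real
cancer-patient cohort would show — and the incremental comparison is a
genuine trade-off (more costly, more effective) for both sexes.

What the synthetic generator does **not** emulate: period-vs-cohort
life-table methodology, non-Gompertz old-age mortality deceleration,
cancer-type or stage structure, and any correlation between mortality and
cause-split errors. Passing tests therefore demonstrate the correctness
and internal coherence of the pipeline on realistically shaped inputs,
not agreement with Statistics Canada data; absolute published totals are
reproducible only with the real life tables and cause-of-death split,
which users can supply as `age,q` / `age,f_cancer` CSVs.

## Numerical choices and degenerate inputs

* Row-stochasticity of every transition matrix is asserted to 1e−12;
  engine-vs-brute-force trace agreement is tested to 1e−10.
* A zero discount rate makes the discounted and undiscounted ledgers
  identical; a frozen cohort (no deaths, no transitions) reproduces the
  35-term geometric sum of discount factors exactly.
* Degenerate parameter ranges (lower = upper) yield point-mass samplers
  and zero tornado swing; b = 0 gives a constant-hazard life table.
* ICERs are reported `None` (with a dominance or undefined flag) rather
  than ±inf; beta fits with infeasible variance degrade to fixed with a
  warning rather than erroring mid-PSA.

## Known limitations

No comorbidity states, no cancer-type/stage stratification, no
second-hand-smoke effects, no EVPI, no multi-way (>2 strategy) frontier,
no currency/CPI handling (costs are consumed as 2015 CAD), and mortality
does not vary with time since diagnosis. The headline PSA uses 10,000
draws (~30 s on one CPU); examples use 2,000 draws for responsiveness.
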