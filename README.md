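# cessation-cea

Cost-effectiveness analysis of smoking-cessation programs for cancer
patients, built as a reusable Markov cohort pipeline.

Roughly one in five newly diagnosed cancer patients is a current smoker,
and continued smoking after diagnosis worsens treatment response,
recurrence risk and survival. This package compares two cessation
strategies for a cohort of 65-year-old smokers with cancer:

* **basic program** — screening for tobacco use, advice and referral
  (one-time administration cost, 4% twelve-month abstinence);
* **best-practice program** — the basic program plus pharmacotherapy
  (varenicline), weekly nurse counseling and follow-up (one-time cost of
  $302 per patient, 24% twelve-month abstinence).

It is aimed at health-economics and health-services researchers who want
a tested, scriptable implementation of the full decision-analytic chain:
life-table mortality adjustment, tunnel-state cohort simulation,
incremental cost-effectiveness, and deterministic + probabilistic
sensitivity analysis.

## Model

A Markov cohort model with yearly cycles follows the cohort from age 65
to 100 over the states *current smoker* (S), *former smoker* (expanded
into one-year tunnel compartments so the annual relapse probability can
depend on years since quitting: 0.24, 0.10, 0.02, 0.021 and 0.005 for
quit durations 1–2, 3–4, 5–8, 9–10 and 10+ years) and *dead*. Each cycle
applies death first (annual probability by age, sex and smoking status),
then quitting or relapse among survivors.

Mortality is derived in six steps from a sex-specific life table q(age)
and the cancer share of deaths f(age): the total hazard m = −ln(1−q) is
split into cancer and non-cancer components, the cancer component is
scaled up to a cancer-patient level, and the smoking-status hazard ratio
(HR 1.50 current, 1.30 former, vs never smokers) scales the non-cancer
component:

    p(age, status) = 1 − exp(−[HR_status · m_noncancer(age) + k · m_cancer(age)])

Costs (annual cancer care $25,058; smoking-attributable $403, retained
through the first four years of abstinence; one-time program costs),
QALYs (EQ-5D utilities by sex/age-band/status minus a 0.12 cancer
decrement) and life-years accrue per cycle, discounted at 5% per year.
The incremental cost-effectiveness ratio is ICER = ΔC/ΔE between the two
programs, dominance is classified first, and cost-effectiveness at a
willingness-to-pay λ is decided by the net monetary benefit
NMB = λ·ΔQALY − ΔCost.

One-way sensitivity analysis re-runs the base case at each parameter's
95% bounds (tornado). Probabilistic sensitivity analysis fits gamma
distributions to costs, beta to probabilities, and lognormal to the
hazard ratios (moment-matched from base value and 95% range), samples
10,000 parameter sets, and summarises the ΔC–ΔQALY cloud as a
cost-effectiveness plane and an acceptability curve (CEAC).

No external data are needed: a synthetic-data module generates
sex-specific Gompertz life tables and cause-of-death splits with the
statistical structure of national life tables, and real tables reshaped
to `age,q` / `age,f_cancer` CSVs drop straight in.

## Worked example

```sh
python examples/run_base_case.py
```

```
--- male cohort of 65-year-old smokers with cancer ---
basic program:         cost $   295,754   QALY   7.21   LY  11.62
best practice program: cost $   296,116   QALY   7.24   LY  11.64
incremental:           cost $    362.23   QALY 0.0374   LY 0.0136
ICER: $9,694/QALY gained, $26,624/LY gained
```

Lifetime discounted cost is dominated by annual cancer care (≈ $25k per
surviving year), so both arms cost nearly $300k; the best-practice
program adds a few hundred dollars (program cost plus the cancer-care
cost of added survival, minus avoided smoking-attributable costs) and
buys 0.037 discounted QALYs — about $9,700 per QALY gained, far below
conventional thresholds. Other entry points:

```sh
python examples/mortality_adjustment.py   # the six-step hazard derivation
python examples/tornado_analysis.py       # one-way sensitivity ranking
python examples/probabilistic_sa.py       # CE plane + acceptability curve
python examples/synthetic_life_tables.py  # the packaged input generator
cessation-cea base-case --sex female --out results/   # CLI front end
```

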