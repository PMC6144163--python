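"""Base-case comparison of the two cessation programs, both sexes.

Builds the packaged synthetic life tables, derives smoking-status-adjusted
mortality, runs the yearly Markov cohort from age 65 to 100 for each
strategy, and prints the discounted totals and incremental ratios.
"""

from cessation_cea import (
    default_cause_split,
    default_life_table,
    default_params,
    evaluate_strategies,
)

params = default_params()
for sex in ("male", "female"):
    lt = default_life_table(sex)
    cs = default_cause_split(sex)
    res = evaluate_strategies(params, lt, cs, sex)
    print(f"--- {sex} cohort of 65-year-old smokers with cancer ---")
    print(f"basic program:         cost ${res.cost_basic:>10,.0f}   "
          f"QALY {res.qaly_basic:6.2f}   LY {res.ly_basic:6.2f}")
    print(f"best practice program: cost ${res.cost_bp:>10,.0f}   "
          f"QALY {res.qaly_bp:6.2f}   LY {res.ly_bp:6.2f}")
    print(f"incremental:           cost ${res.delta_cost:>10,.2f}   "
          f"QALY {res.delta_qaly:.4f}   LY {res.delta_ly:.4f}")
    print(f"ICER: ${res.icer_qaly_rounded:,}/QALY gained, "
          f"${res.icer_ly_rounded:,}/LY gained\n")

print("The best-practice program (varenicline + nurse counseling + follow-up)")
print("costs a few hundred dollars more per patient over a lifetime but buys")
print("extra quality-adjusted survival at well under $10,000 per QALY --")
print("far below conventional willingness-to-pay thresholds.")
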