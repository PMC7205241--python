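"""Base-case incremental analysis at the two scenario drug prices.

Builds the baseline three-state partitioned-survival model (published
log-logistic curves, 28-day cycles, 5-year horizon, 3% discounting) and
compares ramucirumab + paclitaxel against placebo + paclitaxel at the
mainland-China and Beijing willingness-to-pay settings.
"""

import psmcea as m

for scenario, (wtp, price) in {"mainland": (26022.0, 244.0), "beijing": (56263.0, 604.0)}.items():
    bundle = m.default_bundle(ram_price_per_cycle=price)
    ram, pla, cmp_ = m.run_comparison(bundle, wtp)
    print(f"\n--- {scenario}: RAM ${price:.0f}/cycle, WTP ${wtp:,.0f}/QALY ---")
    print(f"RAM arm: cost ${ram.cost:>9,.0f}  LY {ram.life_years:.3f}  QALY {ram.qalys:.3f}")
    print(f"PLA arm: cost ${pla.cost:>9,.0f}  LY {pla.life_years:.3f}  QALY {pla.qalys:.3f}")
    print(f"increments: dC ${cmp_.delta_cost:,.0f}, dLY {cmp_.delta_ly:.4f}, dQALY {cmp_.delta_qaly:.4f}")
    print(f"ICER ${cmp_.icer_per_qaly:,.0f}/QALY (${cmp_.icer_per_ly:,.0f}/LY), NMB ${cmp_.nmb:,.0f}")

# A positive NMB (equivalently ICER < WTP) would mean the combination is
# cost-effective at that threshold; negative NMB means the extra QALYs cost
# more than the threshold values them.
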