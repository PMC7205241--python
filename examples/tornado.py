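"""One-way (tornado) sensitivity analysis of the ICER.

Each economic parameter is moved to the low and high end of its published
range with everything else held at baseline; the bar width is the induced
ICER swing.  Wide bars identify the parameters whose uncertainty matters
most for the cost-effectiveness verdict.
"""

import psmcea as m

bundle = m.default_bundle(ram_price_per_cycle=244.0)
entries = m.tornado(bundle, wtp=26022.0)

print(f"baseline ICER ${entries[0].baseline_icer:,.0f}/QALY (mainland scenario)\n")
print(f"{'parameter':32s} {'low':>10s} {'high':>10s} {'ICER swing':>12s}")
for e in entries[:8]:
    print(
        f"{e.parameter:32s} {e.low_value:>10.3f} {e.high_value:>10.3f} "
        f"${e.width:>10,.0f}"
    )
# Bars are sorted widest-first; an entry's two ICER endpoints come from
# full model re-runs at the parameter's range bounds.
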