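"""One-way sensitivity analysis (tornado).

Each parameter is pushed to its lower and upper limit with everything else
at baseline; bars are sorted by the width of the resulting ICER interval.
"""
from lipidce import default_parameters, generate_life_table, one_way

params = default_parameters()
life = generate_life_table()
wtp = params.settings.wtp

baseline, entries = one_way(params, life)
print(f"baseline ICER ¥{baseline:,.0f}/QALY (WTP ¥{wtp:,.0f})\n")
print(f"{'parameter':28s} {'ICER at low':>14s} {'ICER at high':>14s} {'width':>14s}")
for e in entries[:10]:
    print(f"{e.parameter:28s} {e.icer_at_low:>14,.0f} {e.icer_at_high:>14,.0f} {e.width:>14,.0f}")

flips = [e for e in entries if min(e.icer_at_low, e.icer_at_high) <= wtp]
print(f"\nparameters that flip the verdict: {len(flips)}")
# The MI risk ratio dominates (its 0.48-0.96 CI swings the QALY gain several
# fold); no single parameter variation brings the ICER below the WTP.
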