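"""Price scenarios and the threshold-price search.

The QALY gain is price-invariant, so the ICER falls linearly with the
per-injection price; the search finds where it crosses the WTP ceiling.
"""
from lipidce import default_parameters, generate_life_table, run_scenario, threshold_price

params = default_parameters()
life = generate_life_table()
wtp = params.settings.wtp

for price in (20000.0, 10000.0, 2500.0):
    r = run_scenario(params, life, price)
    print(f"price ¥{price:>8,.0f}/injection -> ICER ¥{r.icer:>12,.2f}/QALY ({r.verdict(wtp)})")

th = threshold_price(params, life, tolerance=1.0)
print(
    f"\nthreshold price ¥{th.threshold_price:,.2f}/injection "
    f"({th.percent_reduction:.1f}% below the ¥20,000 list price), "
    f"achieved ICER ¥{th.achieved_icer:,.2f}/QALY"
)
# Below the threshold price the combination becomes cost-effective at the
# 3x-GDP willingness-to-pay; the required discount is in the high 80s percent.
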