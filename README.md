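# lipidce

Lifetime cost-effectiveness of adding inclisiran — a PCSK9-silencing siRNA
given by subcutaneous injection on day 1, day 90, and then every six months —
to daily statin therapy, versus statin alone, in mainland-Chinese patients
with dyslipidemia and established cardiovascular disease. The package is
aimed at health-economics analysts who want a scriptable, fully tested
replacement for a point-and-click decision-tree model: every input is a
config entry, every analysis is a library call, and every figure-grade
artifact is a plain-text export.

## Model

A discrete-time Markov cohort model with a one-year cycle and four clinical
states — **pre-MI**, **MI**, **post-MI**, **dead** — expanded internally with
tunnel states (`MI_FIRST`, `MI_RECURRENT`, `POST_MI_Y1`, `POST_MI_LATER`) so
that the MI year and the first post-MI year, which carry distinct costs and
utility decrements, last exactly one cycle. Per cycle at age *a*:

- background non-CVD mortality *q(a)* comes from a life table (a calibrated
  Gompertz table with *q*(60) = 0.0042 by default; supply your own CSV to
  override);
- survivors of the pre-MI state suffer a first MI with annual probability
  *p* = 0.0234, reduced in the inclisiran arm on the rate scale,
  *p′* = 1 − (1 − p)^RR with RR = 0.68 (95% CI 0.48–0.96);
- MI-state mortality is 25 × *q(a)* (capped at 1); post-MI mortality is
  max(*q(a)*, 2.1%); recurrent MI occurs at 4.1%/year (also RR-adjusted);
- revascularization (3.2%/year) is an in-cycle event inside the MI year,
  entering costs and utilities in expectation.

Utilities: 0.84 pre-MI, 0.80 after any event, decrements 0.06 (recurrent MI)
and 0.07 (revascularization). Costs (RMB): ¥20,000 per injection + ¥36
injection fee (3 injections in year 1, 2 thereafter), weighted statin cost
¥3.45/day, lab tests ¥211 × 2/year, MI hospitalization ¥30,381.30,
revascularization ¥68,625.60, rehabilitation ¥18,758.50 (first year) /
¥10,800 (later) at 9.96% uptake. Both costs and QALYs are discounted at
5%/year; the willingness-to-pay (WTP) ceiling is 3 × per-capita GDP =
¥257,094/QALY. The headline statistic is the incremental cost-effectiveness
ratio ICER = ΔC/ΔE between the two arms.

Sensitivity machinery: one-way (tornado) analysis over every parameter's
printed bounds; 1,000-draw second-order Monte Carlo PSA (beta for
probabilities and utilities, gamma for costs, log-normal for the RR matched
to its CI, bounds read as 95% intervals so σ = range/3.92); and
cost-effectiveness acceptability curves from the PSA draws via net monetary
benefit. A bracketed search returns the injection price at which the ICER
meets the WTP.

## Worked example

```python
from lipidce import default_parameters, generate_life_table, run_ce, threshold_price

params = default_parameters()
life = generate_life_table()        # synthetic Gompertz life table, q(60)=0.0042
res = run_ce(params, life)
print(res.delta_cost, res.delta_qaly, res.icer)
th = threshold_price(params, life, tolerance=1.0)
print(th.threshold_price, th.percent_reduction)
```

Running `python examples/01_basecase.py` prints:

```
inclisiran + statin: cost ¥564,897.02, QALYs 10.76
statin alone:        cost ¥31,898.77, QALYs 10.49
incremental cost  ¥532,998.26 ($79,243.28)
incremental QALYs 0.2748
ICER              ¥1,939,294.82/QALY vs WTP ¥257,094.00/QALY
verdict: not cost-effective
```

The lifetime QALY gain from adding inclisiran is about 0.27, while nearly
all of the ¥533k incremental cost is drug cost, putting the ICER at ~7.5×
the WTP ceiling: not cost-effective at the ¥20,000 list price. At a ¥2,500
scenario price the ICER falls to ¥236,702/QALY (just under the ceiling), and
the threshold search (`examples/02_price_scenarios.py`) puts the break-even
price at ¥2,709.60/injection — an 86.5% reduction from list. The tornado
(`examples/03_tornado.py`) is dominated by the MI risk ratio, with no single
parameter flipping the verdict, and the PSA (`examples/04_psa_ceac.py`)
gives a 0% probability of cost-effectiveness at the WTP at list price versus
roughly half the draws at ¥2,500.

The other examples cover the PSA/CEAC and the synthetic registry; the same
analyses are available from the shell via the `lipidce` CLI
(`basecase`, `owsa`, `psa`, `threshold`, `synth`), which writes CSV/JSON
outputs plus a run manifest.

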