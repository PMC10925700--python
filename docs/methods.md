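# Methods

## Cohort model

The model follows a closed cohort of dyslipidemia patients with established
cardiovascular disease from a start age of 60 (the statin cohort's mean age
is 59.8) to a terminal age of 100, in one-year cycles. The public state
space — pre-MI, MI, post-MI, dead — is expanded internally so the Markov
property holds with time-dependent rewards:

| internal state | meaning | duration |
|---|---|---|
| `PRE_MI` | event-free on therapy | unbounded |
| `MI_FIRST` | the year of a first MI | exactly 1 cycle |
| `MI_RECURRENT` | the year of a recurrent MI | exactly 1 cycle |
| `POST_MI_Y1` | first year after an MI year | exactly 1 cycle |
| `POST_MI_LATER` | subsequent post-MI years | unbounded |
| `DEAD` | absorbing | — |

Within a cycle, death is resolved first and event probabilities apply to
survivors: the pre-MI row is (q, (1−q)·p_MI, remainder), which keeps every
row stochastic without renormalisation. The engine asserts row sums and
cohort mass conservation to 1e-9 every cycle.

Competing mortality assumptions: MI-year death is a multiplier on background
mortality (25 × q, capped at 1 — the cap binds above roughly age 95 on the
default life table); post-MI death is max(q, 2.1%), because a flat 2.1%
would otherwise fall below background mortality from about age 72 onward.
Config flags (`mi_mortality_fixed`, `post_mi_mortality_flat`) switch either
to its literal flat reading.

The MI risk ratio (0.68) is applied on the rate scale, p′ = 1 − (1−p)^RR,
consistent with the exponential-hazard rate↔probability conversion used for
all annual inputs; it applies to both first and recurrent MI in the
inclisiran arm (`rr_applies_to_recurrence: false` restricts it to first MI).
Revascularization is not a separate state: it is an in-cycle event inside
the MI year, contributing 3.2% × ¥68,625.60 to cost and 3.2% × 0.07 to the
utility decrement in expectation.

No half-cycle correction is applied; cycle k is discounted by (1+r)^(−k)
with the first year undiscounted. State membership at the start of a cycle
earns that cycle's full rewards. These conventions are pinned by tests
(closed-form geometric series in the no-event limit, matched to 1e-9) and by
a 100,000-patient per-individual microsimulation that must agree with the
cohort expectations within 3 Monte-Carlo standard errors.

## Parameters

All point values, bounds, and distribution families live in
`src/lipidce/data/default_config.yaml`. Costs are in RMB (USD derived only
at presentation, at the 2022 rate of 6.7261 RMB/USD); a `cpi_factor_to_2023`
multiplier (default 1.0, since no medical-care CPI multiplier is published)
inflates all costs and their bounds together. Parameters without printed
bounds (the two utility decrements, the injection fee if made uncertain)
default to ±20% of baseline. The weighted statin daily cost ¥3.45 is
reconstructed from the price table by averaging each drug's per-day prices,
rounding the averages to the 1-dp precision at which daily prices are
quoted, and weighting by renormalised usage shares (45.41/58.58/13.22 →
38.74%/49.98%/11.28%); exact (unrounded) weighting gives ¥3.456 and is
available via `round_averages_to=None`. Fluvastatin (0.03% usage) is
excluded from the weighting.

Inclisiran dosing is 3 injections in year 1 (day 1, day 90, day 270) and 2
per year thereafter — the per-year counts follow from the printed schedule
and are config-exposed, as is the lab-test frequency (2 visits/year, both
arms). Statin years are 365 days. The combination arm keeps paying statin
and monitoring costs.

## Life table

No census life table is published with the model inputs, so the default is
an explicitly synthetic Gompertz table q(age) = min(1, a·e^(b·age)),
calibrated so q(60) = 0.0042 (the representative non-CVD mortality, the
midpoint of the printed 3.36‰–5.04‰ band) and q(100) = 1 (forced
absorption). This gives b ≈ 0.137, a steeper old-age slope than typical
national tables — a consequence of pinning absorption at 100 — which mainly
shortens the far tail of the survival curve. A user-supplied CSV life table
takes precedence everywhere. The representative-mortality sensitivity
parameter rescales the whole table proportionally (capped at 1).

Because the published analysis's life table, start age, and cycle-correction
convention are not printed, its exact lifetime totals are not reproducible;
this package's results agree with it structurally (QALY gain of ~0.2–0.3,
base-case ICER several times the WTP, scenario ICER near the WTP, threshold
reduction in the high 80s percent) rather than digit-for-digit.

## Sensitivity analyses

**One-way.** Each parameter in turn is set to its lower and upper bound
(all others at baseline) and both arms re-run; entries are sorted by the
width of the ICER interval. The discount rate varies over 0–8% in the
tornado but is never sampled in the PSA (no distribution is assigned to it).

**PSA.** 1,000 second-order Monte Carlo draws by default (seeded,
reproducible). Probabilities and utilities are beta, costs gamma, both
moment-matched with sd = (high − low)/3.92 — printed bounds are read as
central 95% intervals (`range_to_sd_divisor: 4.0` switches to the ±2σ
reading). The MI risk ratio is log-normal matched to its 95% CI
(0.48–0.96): a ratio whose CI reaches toward 1 cannot be represented by a
beta on [0,1] without distorting the upper tail. The MI-mortality handle is
sampled as the MI-death probability at the representative background
mortality (baseline 0.105 = 25 × 0.0042, bounds 0.084–0.126) and applied by
rescaling the multiplier, preserving the age structure. Parameters are
sampled independently; no correlation structure is assumed. Overriding a
parameter (e.g. a scenario price) rescales its uncertainty bounds
proportionally, so a ¥2,500-scenario PSA samples around ¥2,500.

**CEAC.** At each WTP on a 0–600k grid (10k steps, always containing the
¥257,094 threshold), the acceptability is the fraction of draws in which the
inclisiran arm has strictly higher net monetary benefit; ties count as not
cost-effective. A brute-force recount over raw draws is asserted equal in
tests.

**Threshold price.** The incremental cost is linear in the injection price
(slope = discounted expected injections) and the QALY gain is
price-invariant, so the ICER crosses the WTP once; `brentq` on
ΔC − WTP·ΔE over [0, list price] refines until the achieved ICER is within
1 RMB/QALY (configurable) of the WTP. Non-bracketing cases return boundary
reports (`already_cost_effective`, `not_attainable`) instead of raising.

## Synthetic registry

`generate_registry` emulates the two-group hospital registry: group sizes
27,785 / 121; age from truncated normals whose *truncated* moments match the
targets (59.82 ± 14.54 and 53.26 ± 10.50); LDL-C from a gamma shifted to the
1.81 mmol/L eligibility floor with exact target mean/SD — a left-truncated
normal cannot attain these SDs (a truncated normal's SD is bounded by the
mean-to-floor gap, and the inclisiran group's 2.80 ± 1.46 violates that
bound), and the right-skewed shape is the more realistic one for lipid
levels. Sex and prior-MI are Bernoulli at target rates (61.24%/69.42% male;
2.34% MI, statin group only — MI is unobserved in the small inclisiran
group and set false); rehabilitation is Bernoulli (9.96%) among prior-MI
patients. Overlapping statin usage (45.41/58.58/13.22/0.03%, summing past
100%) is reproduced exactly in expectation by sampling per-drug Bernoullis
at down-scaled probabilities p·c and rejecting empty sets, where c solves
c = 1 − Π(1 − p·c), so that conditioning on a nonempty set restores the
target marginals.

The registry's MI column is a prevalence snapshot used as an annual
incidence proxy, mirroring how the source figure enters the model — a
fidelity choice, not an endorsement. `estimate_mi_incidence` attaches a
Wilson 95% interval (statsmodels).

What the synthetic data does **not** emulate: correlations between age,
sex, LDL-C and MI history; treatment effects on LDL-C; calendar trends;
and any real census mortality structure beyond the single calibrated
anchor. Passing recovery tests therefore demonstrates that the estimators
and pipeline are correct on data with the published marginal structure,
not that the model's inputs are externally valid.

## Problem sizes and numerics

Default analyses use the full 40-cycle horizon; the test suite runs the
microsimulation cross-check at 100,000 patients, distribution moment checks
at 10⁶ draws, registry recovery at the published sample sizes, and PSA
checks at 100–1,000 draws. Degenerate inputs are rejected with named
errors: rates/probabilities outside [0,1), nonpositive relative risks or
exchange rates, all-zero usage shares, infeasible beta moments
(sd² ≥ mean(1−mean)), empty registry groups, non-contiguous or
non-absorbing life tables. Ties in the CEAC count against the intervention;
the threshold search reports boundaries rather than extrapolating.
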