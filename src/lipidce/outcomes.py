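"""Arm comparison: incremental cost, incremental QALYs, ICER, net monetary
benefit, price scenarios, and the threshold-price search at the
willingness-to-pay ceiling (3x per-capita GDP)."""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.optimize import brentq

from .lifetable import LifeTable
from .markov import ArmResult, run_arm
from .params import ModelParameters, rmb_to_usd

__all__ = [
    "CEResult",
    "ThresholdResult",
    "compare",
    "net_monetary_benefit",
    "wtp_threshold",
    "run_ce",
    "run_scenario",
    "threshold_price",
    "results_table",
]


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of the inclisiran + statin arm against statin
    alone.  ``icer`` is defined only for the cost-more/gains-more quadrant;
    dominance is labelled instead of reporting a sign-ambiguous ratio."""

    cost_inclisiran: float
    cost_statin: float
    qaly_inclisiran: float
    qaly_statin: float
    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str | None   # 'dominant', 'dominated', or None

    def verdict(self, wtp: float) -> str:
        if self.dominance == "dominant":
            return "cost-effective (dominant)"
        if self.dominance == "dominated":
            return "not cost-effective (dominated)"
        if self.icer is None:
            return "no ICER (equal effectiveness); compare costs"
        return "cost-effective" if self.icer <= wtp else "not cost-effective"


def compare(intervention: ArmResult, comparator: ArmResult) -> CEResult:
    """Incremental cost-effectiveness of ``intervention`` over ``comparator``."""
    dc = intervention.discounted_cost - comparator.discounted_cost
    dq = intervention.discounted_qaly - comparator.discounted_qaly
    icer: float | None = None
    dominance: str | None = None
    if dq > 0 and dc <= 0:
        dominance = "dominant"
    elif dq < 0 and dc >= 0:
        dominance = "dominated"
    elif dq != 0:
        icer = dc / dq
    return CEResult(
        cost_inclisiran=intervention.discounted_cost,
        cost_statin=comparator.discounted_cost,
        qaly_inclisiran=intervention.discounted_qaly,
        qaly_statin=comparator.discounted_qaly,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        dominance=dominance,
    )


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = QALY x WTP - cost; ranking two arms by NMB at a given WTP agrees
    with the ICER-versus-WTP verdict whenever the QALY increment is positive."""
    if wtp < 0:
        raise ValueError("willingness to pay must be nonnegative")
    return qaly * wtp - cost


def wtp_threshold(gdp_per_capita: float) -> float:
    """Willingness-to-pay ceiling: three times per-capita GDP (RMB/QALY)."""
    if gdp_per_capita < 0:
        raise ValueError("GDP per capita must be nonnegative")
    if gdp_per_capita == 0:
        warnings.warn("GDP per capita is zero; WTP threshold degenerates to 0")
    return 3.0 * gdp_per_capita


def run_ce(params: ModelParameters, life: LifeTable) -> CEResult:
    """Run both arms under one parameter bundle and compare them."""
    return compare(run_arm("inclisiran", params, life), run_arm("statin", params, life))


def run_scenario(
    params: ModelParameters, life: LifeTable, price_override: float
) -> CEResult:
    """Re-run the comparison with the inclisiran per-injection price replaced.

    Only the inclisiran arm's costs move; the statin arm and both arms'
    QALYs are unchanged by construction.
    """
    if price_override < 0:
        raise ValueError("price override must be nonnegative")
    return run_ce(params.with_overrides({"inclisiran_per_injection": price_override}), life)


@dataclass(frozen=True)
class ThresholdResult:
    threshold_price: float      # RMB per injection
    percent_reduction: float    # % below the list price
    achieved_icer: float | None
    boundary: str | None        # 'already_cost_effective' | 'not_attainable' | None


def threshold_price(
    params: ModelParameters,
    life: LifeTable,
    wtp: float | None = None,
    tolerance: float = 1.0,
) -> ThresholdResult:
    """Largest inclisiran price at which the combination is cost-effective.

    The incremental cost is linear in the injection price with a positive
    slope (the discounted expected number of injections) and the QALY
    increment is price-invariant, so the ICER crosses the WTP exactly once;
    the root is found by bracketed search on [0, list price] and refined
    until the achieved ICER is within ``tolerance`` RMB/QALY of the WTP.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if wtp is None:
        wtp = params.settings.wtp
    list_price = params.costs.inclisiran_per_injection
    statin = run_arm("statin", params, life)

    def result_at(price: float) -> CEResult:
        inc = run_arm(
            "inclisiran",
            params.with_overrides({"inclisiran_per_injection": price}),
            life,
        )
        return compare(inc, statin)

    def gap(price: float) -> float:
        r = result_at(price)
        # delta_qaly > 0 and constant; gap sign matches (ICER - WTP) sign
        return r.delta_cost - wtp * r.delta_qaly

    at_list = result_at(list_price)
    if at_list.delta_qaly <= 0:
        raise RuntimeError("threshold search requires a positive QALY increment")
    if gap(list_price) <= 0:
        return ThresholdResult(list_price, 0.0, at_list.icer, "already_cost_effective")
    if gap(0.0) > 0:
        at_zero = result_at(0.0)
        return ThresholdResult(0.0, 100.0, at_zero.icer, "not_attainable")

    # xtol chosen so |ICER - WTP| = |gap| / dq is comfortably inside tolerance
    xtol = max(tolerance * at_list.delta_qaly / 100.0, 1e-8)
    price = float(brentq(gap, 0.0, list_price, xtol=xtol))
    achieved = result_at(price)
    # ratio taken directly: at the root the quadrant label is fp-fragile
    achieved_icer = achieved.delta_cost / achieved.delta_qaly
    if abs(achieved_icer - wtp) > tolerance:
        raise RuntimeError("threshold refinement did not reach the requested tolerance")
    return ThresholdResult(
        threshold_price=price,
        percent_reduction=(list_price - price) / list_price * 100.0,
        achieved_icer=achieved_icer,
        boundary=None,
    )


def results_table(results: dict[str, CEResult], exchange_rate: float) -> pd.DataFrame:
    """Flat results table (one row per scenario label) with RMB and USD
    columns, mirroring the published layout."""
    rows = []
    for label, r in results.items():
        rows.append(
            {
                "scenario": label,
                "cost_inclisiran_rmb": r.cost_inclisiran,
                "cost_inclisiran_usd": rmb_to_usd(r.cost_inclisiran, exchange_rate),
                "cost_statin_rmb": r.cost_statin,
                "cost_statin_usd": rmb_to_usd(r.cost_statin, exchange_rate),
                "delta_cost_rmb": r.delta_cost,
                "delta_cost_usd": rmb_to_usd(r.delta_cost, exchange_rate),
                "qaly_inclisiran": r.qaly_inclisiran,
                "qaly_statin": r.qaly_statin,
                "delta_qaly": r.delta_qaly,
                "icer_rmb_per_qaly": r.icer,
                "icer_usd_per_qaly": None if r.icer is None else rmb_to_usd(r.icer, exchange_rate),
                "dominance": r.dominance,
            }
        )
    return pd.DataFrame(rows)
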