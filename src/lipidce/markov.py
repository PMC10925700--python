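"""Lifetime Markov cohort engine.

Four clinical states — pre-MI, MI, post-MI, dead — expanded internally with
tunnel states so that the MI year and the first post-MI year (which carry
different costs and utility decrements) last exactly one cycle:

    PRE_MI -> MI_FIRST -> POST_MI_Y1 -> POST_MI_LATER -> (MI_RECURRENT ->
    POST_MI_Y1 ...) with DEAD absorbing from every state.

Cycle length is one year; the cohort starts fully in PRE_MI at ``start_age``
and is run to ``max_age``.  Death is resolved first within a cycle and event
probabilities apply to survivors, which keeps every row stochastic without
renormalisation.  No half-cycle correction is applied; the first cycle is
undiscounted (discount exponent k = 0).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .params import (
    ModelParameters,
    annual_drug_and_monitoring_cost,
    apply_relative_risk,
)

__all__ = [
    "STATES",
    "PUBLIC_STATE",
    "ARMS",
    "CohortTrace",
    "ArmResult",
    "build_transition_matrix",
    "run_cohort",
    "discount_factor",
    "cycle_rewards",
    "state_rewards",
    "summarize",
    "run_arm",
]

STATES = ("PRE_MI", "MI_FIRST", "MI_RECURRENT", "POST_MI_Y1", "POST_MI_LATER", "DEAD")
IDX = {s: i for i, s in enumerate(STATES)}
PUBLIC_STATE = {
    "PRE_MI": "PRE_MI",
    "MI_FIRST": "MI",
    "MI_RECURRENT": "MI",
    "POST_MI_Y1": "POST_MI",
    "POST_MI_LATER": "POST_MI",
    "DEAD": "DEAD",
}
ARMS = ("statin", "inclisiran")

_ROW_TOL = 1e-9


def build_transition_matrix(
    age: int, arm: str, params: ModelParameters, life: LifeTable
) -> np.ndarray:
    """Per-cycle transition matrix over the internal states at one age.

    Background (non-CVD) mortality q(age) comes from the life table, scaled
    by the representative-mortality parameter.  MI-state death is a
    multiplier on q (default 25x, capped at 1); post-MI death is
    max(q, flat post-MI probability) so it never falls below background
    mortality at old ages.  In the inclisiran arm the MI risk ratio is
    applied on the rate scale to first (and, by default, recurrent) MI.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    tr = params.transitions
    q = min(1.0, life.q_at(age) * tr.noncvd_scale)

    p_mi = tr.mi_incidence_statin
    p_rec = tr.p_recurrence
    if arm == "inclisiran":
        p_mi = apply_relative_risk(p_mi, tr.rr_mi_inclisiran) if p_mi > 0 else 0.0
        if tr.rr_applies_to_recurrence and p_rec > 0:
            p_rec = apply_relative_risk(p_rec, tr.rr_mi_inclisiran)

    if tr.mi_mortality_fixed:
        d_mi = tr.mi_mortality_at_ref
    else:
        d_mi = min(1.0, tr.mi_mortality_multiplier * q)
    d_post = tr.post_mi_mortality if tr.post_mi_mortality_flat else max(q, tr.post_mi_mortality)

    m = np.zeros((6, 6))
    # PRE_MI: die of non-CVD causes, else first MI, else stay
    m[IDX["PRE_MI"], IDX["DEAD"]] = q
    m[IDX["PRE_MI"], IDX["MI_FIRST"]] = (1 - q) * p_mi
    m[IDX["PRE_MI"], IDX["PRE_MI"]] = (1 - q) * (1 - p_mi)
    # MI tunnel states: die of MI, else move on to the first post-MI year
    for s in ("MI_FIRST", "MI_RECURRENT"):
        m[IDX[s], IDX["DEAD"]] = d_mi
        m[IDX[s], IDX["POST_MI_Y1"]] = 1 - d_mi
    # post-MI states: die, else recurrent MI, else settle into later post-MI
    for s in ("POST_MI_Y1", "POST_MI_LATER"):
        m[IDX[s], IDX["DEAD"]] = d_post
        m[IDX[s], IDX["MI_RECURRENT"]] = (1 - d_post) * p_rec
        m[IDX[s], IDX["POST_MI_LATER"]] = (1 - d_post) * (1 - p_rec)
    m[IDX["DEAD"], IDX["DEAD"]] = 1.0

    if np.any(m < 0) or np.any(m > 1):
        raise RuntimeError(f"transition probability outside [0, 1] at age {age}")
    if np.max(np.abs(m.sum(axis=1) - 1.0)) > _ROW_TOL:
        raise RuntimeError(f"transition matrix rows do not sum to 1 at age {age}")
    return m


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy proportions per cycle; row k is the start of cycle k."""

    arm: str
    occupancy: np.ndarray   # (n_cycles + 1, 6)
    ages: np.ndarray        # (n_cycles + 1,) age at the start of each cycle

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(df)))
        return df


def run_cohort(arm: str, params: ModelParameters, life: LifeTable) -> CohortTrace:
    """Propagate the cohort from ``start_age`` to ``max_age`` one year at a
    time, checking mass conservation every cycle."""
    st = params.settings
    horizon = st.max_age - st.start_age
    occ = np.zeros((horizon + 1, 6))
    occ[0, IDX["PRE_MI"]] = 1.0
    n = horizon
    for k in range(horizon):
        m = build_transition_matrix(st.start_age + k, arm, params, life)
        occ[k + 1] = occ[k] @ m
        if abs(occ[k + 1].sum() - 1.0) > _ROW_TOL:
            raise RuntimeError(f"cohort mass not conserved at cycle {k}")
        if occ[k + 1, IDX["DEAD"]] > 1.0 - 1e-9:
            n = k + 1
            break
    occ = occ[: n + 1]
    ages = st.start_age + np.arange(n + 1)
    return CohortTrace(arm=arm, occupancy=occ, ages=ages)


def discount_factor(k: int, rate: float) -> float:
    """Discount factor ``(1 + rate)^-k`` for cycle index k (first cycle k=0
    is undiscounted)."""
    if rate < 0:
        raise ValueError("discount rate must be nonnegative")
    return (1.0 + rate) ** (-k)


def cycle_rewards(
    state: str, arm: str, year_index: int, params: ModelParameters
) -> tuple[float, float]:
    """(cost in RMB, utility weight) accrued by one person spending cycle
    ``year_index`` (1-based) in ``state``.

    Revascularization is an in-cycle event within the MI year: its cost and
    utility decrement enter as expectations weighted by the annual
    revascularization probability.  Rehabilitation cost enters the post-MI
    states weighted by the rehabilitation uptake rate.
    """
    if state == "DEAD":
        return 0.0, 0.0
    c, u, tr = params.costs, params.utilities, params.transitions
    base = annual_drug_and_monitoring_cost(arm, year_index, c, params.settings)
    if state == "PRE_MI":
        return base, u.u_pre_mi
    if state in ("MI_FIRST", "MI_RECURRENT"):
        cost = base + c.mi_hospitalization_annual + tr.p_revasc * c.revascularization
        util = u.u_post_event - tr.p_revasc * u.dec_revasc
        if state == "MI_RECURRENT":
            util -= u.dec_recurrent_mi
        return cost, util
    if state == "POST_MI_Y1":
        return base + tr.rehab_rate * c.rehab_first_year, u.u_post_event
    if state == "POST_MI_LATER":
        return base + tr.rehab_rate * c.rehab_later_years, u.u_post_event
    raise ValueError(f"unknown state {state!r}")


def state_rewards(arm: str, year_index: int, params: ModelParameters):
    """Vectorised rewards: (costs, utilities) arrays aligned with STATES."""
    pairs = [cycle_rewards(s, arm, year_index, params) for s in STATES]
    return np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs])


@dataclass(frozen=True)
class ArmResult:
    arm: str
    discounted_cost: float
    discounted_qaly: float
    life_years: float           # undiscounted expected years alive
    ledger: pd.DataFrame        # per-cycle accounting

    def __post_init__(self) -> None:
        if self.discounted_qaly > self.life_years + 1e-9:
            raise RuntimeError("QALYs exceed life years (utility > 1 somewhere)")


def summarize(trace: CohortTrace, params: ModelParameters) -> ArmResult:
    """Accrue discounted costs and QALYs over a cohort trace.

    State membership at the start of cycle k earns that cycle's rewards,
    discounted by (1 + r)^-k.
    """
    rate = params.settings.discount_rate
    rows = []
    total_cost = total_qaly = total_ly = 0.0
    for k in range(trace.n_cycles):
        occ = trace.occupancy[k]
        costs, utils = state_rewards(trace.arm, k + 1, params)
        f = discount_factor(k, rate)
        cost_k = float(occ @ costs)
        qaly_k = float(occ @ utils)
        alive = float(1.0 - occ[IDX["DEAD"]])
        total_cost += f * cost_k
        total_qaly += f * qaly_k
        total_ly += alive
        rows.append(
            {
                "cycle": k,
                "age": int(trace.ages[k]),
                "alive": alive,
                "cost": cost_k,
                "utility": qaly_k,
                "discount": f,
                "disc_cost": f * cost_k,
                "disc_qaly": f * qaly_k,
            }
        )
    return ArmResult(
        arm=trace.arm,
        discounted_cost=total_cost,
        discounted_qaly=total_qaly,
        life_years=total_ly,
        ledger=pd.DataFrame(rows),
    )


def run_arm(arm: str, params: ModelParameters, life: LifeTable) -> ArmResult:
    """Convenience: run the cohort and summarise it in one call."""
    return summarize(run_cohort(arm, params, life), params)
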