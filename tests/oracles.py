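"""Independent oracles used by the test suite.

The microsimulation propagates individual patients through the same per-age
transition matrices and cycle rewards as the cohort engine, but by sampling
state paths rather than multiplying occupancy vectors.  Its Monte-Carlo mean
discounted cost and QALY estimate the same expectations the cohort trace
computes analytically, so agreement within Monte-Carlo error cross-checks
the cohort algebra end to end.
"""
from __future__ import annotations

import numpy as np

from lipidce.markov import (
    IDX,
    build_transition_matrix,
    discount_factor,
    state_rewards,
)


def microsimulate(arm, params, life, n_patients=100_000, seed=0):
    """Per-individual discrete-time simulation.

    Returns (mean_cost, mean_qaly, se_cost, se_qaly) over ``n_patients``
    simulated lifetimes.
    """
    st = params.settings
    horizon = st.max_age - st.start_age
    rate = st.discount_rate
    cum = [
        build_transition_matrix(st.start_age + k, arm, params, life).cumsum(axis=1)
        for k in range(horizon)
    ]
    rewards = [state_rewards(arm, k + 1, params) for k in range(horizon)]

    rng = np.random.default_rng(seed)
    state = np.full(n_patients, IDX["PRE_MI"], dtype=np.int64)
    cost = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    for k in range(horizon):
        c_k, u_k = rewards[k]
        f = discount_factor(k, rate)
        cost += f * c_k[state]
        qaly += f * u_k[state]
        u01 = rng.random(n_patients)
        rowcum = cum[k][state]                       # (n, 6)
        state = (rowcum <= u01[:, None]).sum(axis=1)
    return (
        cost.mean(),
        qaly.mean(),
        cost.std(ddof=1) / np.sqrt(n_patients),
        qaly.std(ddof=1) / np.sqrt(n_patients),
    )
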