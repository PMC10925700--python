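"""One-way (tornado) and probabilistic sensitivity analyses.

The one-way analysis reruns the full two-arm model at each parameter's lower
and upper bound, holding everything else at baseline, and sorts parameters by
the width of the resulting ICER interval.

The probabilistic analysis is a second-order Monte Carlo: each draw samples
every uncertain parameter from its fitted distribution — beta for
probabilities and utilities, gamma for costs, log-normal for the MI risk
ratio (matched to its printed 95% CI) — runs both arms deterministically, and
records discounted (cost, QALY) pairs, from which the cost-effectiveness
acceptability curve is computed as the fraction of draws with higher net
monetary benefit in the inclisiran arm at each willingness-to-pay value.

Printed low/high bounds are treated as a central 95% interval, so the fitted
standard deviation is (high - low)/3.92 by default (config-switchable).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .outcomes import CEResult, compare, run_ce
from .markov import run_arm
from .params import ModelParameters, ParameterSpec

__all__ = [
    "TornadoEntry",
    "DistributionSpec",
    "PSAResult",
    "CEACCurve",
    "fit_beta",
    "fit_gamma",
    "fit_lognormal_from_ci",
    "make_distribution",
    "one_way",
    "run_psa",
    "ceac",
    "default_wtp_grid",
]


@dataclass(frozen=True)
class DistributionSpec:
    family: str            # beta | gamma | lognormal | fixed
    a: float               # alpha / shape / mu(log) / value
    b: float = 0.0         # beta / scale / sigma(log) / unused

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size=size)
        if self.family == "lognormal":
            return rng.lognormal(self.a, self.b, size=size)
        if self.family == "fixed":
            return self.a if size is None else np.full(size, self.a)
        raise ValueError(f"unknown family {self.family!r}")

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.b
        if self.family == "lognormal":
            return math.exp(self.a + self.b**2 / 2)
        return self.a


def fit_beta(mean: float, low: float, high: float, divisor: float = 3.92) -> DistributionSpec:
    """Method-of-moments beta fit with sd = (high - low)/divisor.

    alpha = mean (mean(1-mean)/sd^2 - 1), beta = alpha (1-mean)/mean.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"beta mean must be in (0, 1), got {mean}")
    if low >= high:
        raise ValueError("low must be below high")
    sd = (high - low) / divisor
    if sd**2 >= mean * (1 - mean):
        raise ValueError(
            f"infeasible beta moments: sd^2={sd**2:.4g} >= mean(1-mean)="
            f"{mean * (1 - mean):.4g}; narrow the range or change the divisor"
        )
    alpha = mean * (mean * (1 - mean) / sd**2 - 1)
    beta = alpha * (1 - mean) / mean
    return DistributionSpec("beta", alpha, beta)


def fit_gamma(mean: float, low: float, high: float, divisor: float = 3.92) -> DistributionSpec:
    """Method-of-moments gamma fit: shape = mean^2/sd^2, scale = sd^2/mean."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be positive, got {mean}")
    if low >= high:
        raise ValueError("low must be below high")
    sd = (high - low) / divisor
    return DistributionSpec("gamma", mean**2 / sd**2, sd**2 / mean)


def fit_lognormal_from_ci(low: float, high: float) -> DistributionSpec:
    """Log-normal matched to a 95% CI: mu at the geometric CI midpoint,
    sigma = (ln high - ln low)/3.92.  Used for the MI risk ratio, whose CI
    upper bound approaches 1 and which a beta distribution cannot represent
    above 1."""
    if not 0 < low < high:
        raise ValueError("CI bounds must be positive with low < high")
    mu = (math.log(low) + math.log(high)) / 2
    sigma = (math.log(high) - math.log(low)) / 3.92
    return DistributionSpec("lognormal", mu, sigma)


def make_distribution(spec: ParameterSpec, divisor: float = 3.92) -> DistributionSpec:
    """Distribution for one parameter spec, respecting its declared family."""
    if spec.family == "fixed" or not spec.varied:
        return DistributionSpec("fixed", spec.baseline)
    if spec.family == "beta":
        return fit_beta(spec.baseline, spec.low, spec.high, divisor)
    if spec.family == "gamma":
        return fit_gamma(spec.baseline, spec.low, spec.high, divisor)
    if spec.family == "lognormal":
        return fit_lognormal_from_ci(spec.low, spec.high)
    raise ValueError(f"{spec.name}: unknown family {spec.family!r}")


# ---------------------------------------------------------------------------
# one-way (tornado)

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def _icer_value(result: CEResult) -> float:
    if result.icer is not None:
        return result.icer
    # dominance at an extreme bound: sign the ratio for plotting purposes
    if result.dominance == "dominant":
        return -math.inf
    if result.dominance == "dominated":
        return math.inf
    return math.nan


def one_way(
    params: ModelParameters, life: LifeTable
) -> tuple[float, list[TornadoEntry]]:
    """Tornado analysis: (baseline ICER, entries sorted by descending width).

    Every spec with a nondegenerate range is varied; zero-width parameters
    are retained with width 0.
    """
    base = run_ce(params, life)
    baseline_icer = _icer_value(base)
    entries = []
    for name, spec in params.specs.items():
        if not spec.varied:
            entries.append(
                TornadoEntry(name, spec.low, spec.high, baseline_icer, baseline_icer)
            )
            continue
        icer_lo = _icer_value(run_ce(params.with_overrides({name: spec.low}), life))
        icer_hi = _icer_value(run_ce(params.with_overrides({name: spec.high}), life))
        entries.append(TornadoEntry(name, spec.low, spec.high, icer_lo, icer_hi))
    entries.sort(key=lambda e: e.width, reverse=True)
    return baseline_icer, entries


def tornado_frame(baseline_icer: float, entries: list[TornadoEntry]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "value_low": e.low,
                "value_high": e.high,
                "icer_at_low": e.icer_at_low,
                "icer_at_high": e.icer_at_high,
                "width": e.width,
            }
            for e in entries
        ]
    )
    df.attrs["baseline_icer"] = baseline_icer
    return df


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass(frozen=True)
class PSAResult:
    seed: int
    draws: pd.DataFrame   # columns: cost_statin, qaly_statin, cost_inclisiran, qaly_inclisiran

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    @property
    def delta_cost(self) -> np.ndarray:
        return (self.draws["cost_inclisiran"] - self.draws["cost_statin"]).to_numpy()

    @property
    def delta_qaly(self) -> np.ndarray:
        return (self.draws["qaly_inclisiran"] - self.draws["qaly_statin"]).to_numpy()


def run_psa(
    params: ModelParameters,
    life: LifeTable,
    n: int | None = None,
    seed: int | None = None,
) -> PSAResult:
    """Second-order Monte Carlo over all uncertain parameters.

    Each draw jointly samples every non-fixed parameter (independently — no
    correlation structure is assumed), then evaluates both arms with the
    sampled bundle.  Fully reproducible from ``seed``.
    """
    n = params.n_psa if n is None else n
    seed = params.psa_seed if seed is None else seed
    if n < 1:
        raise ValueError("number of PSA draws must be >= 1")
    dists = {}
    for name, spec in params.specs.items():
        if name == "discount_rate":    # varied in one-way analysis only
            continue
        try:
            d = make_distribution(spec, params.range_to_sd_divisor)
        except ValueError as exc:
            raise ValueError(f"cannot sample parameter {name!r}: {exc}") from exc
        if d.family != "fixed":
            dists[name] = d
    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n):
        overrides = {name: float(d.sample(rng)) for name, d in dists.items()}
        drawn = params.with_overrides(overrides)
        inc = run_arm("inclisiran", drawn, life)
        sta = run_arm("statin", drawn, life)
        records.append(
            (sta.discounted_cost, sta.discounted_qaly, inc.discounted_cost, inc.discounted_qaly)
        )
    draws = pd.DataFrame(
        records,
        columns=["cost_statin", "qaly_statin", "cost_inclisiran", "qaly_inclisiran"],
    )
    if not np.all(np.isfinite(draws.to_numpy())):
        raise RuntimeError("non-finite values in PSA draws")
    return PSAResult(seed=seed, draws=draws)


@dataclass(frozen=True)
class CEACCurve:
    wtp: np.ndarray
    probability: np.ndarray

    def at(self, wtp: float) -> float:
        idx = np.nonzero(np.isclose(self.wtp, wtp))[0]
        if idx.size == 0:
            raise KeyError(f"wtp {wtp} not on the curve grid")
        return float(self.probability[idx[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def default_wtp_grid(wtp: float = 257094.0) -> np.ndarray:
    """0 to 600k RMB/QALY in 10k steps, always including the WTP threshold."""
    grid = np.arange(0.0, 600001.0, 10000.0)
    if not np.any(np.isclose(grid, wtp)):
        grid = np.sort(np.append(grid, wtp))
    return grid


def ceac(psa: PSAResult, wtp_grid: np.ndarray) -> CEACCurve:
    """Acceptability at each WTP: fraction of draws where the inclisiran arm
    has strictly higher net monetary benefit (ties count as not
    cost-effective)."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("WTP grid is empty")
    dq = psa.delta_qaly[None, :]
    dc = psa.delta_cost[None, :]
    prob = np.mean(wtp_grid[:, None] * dq - dc > 0, axis=1)
    return CEACCurve(wtp=wtp_grid, probability=prob)
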