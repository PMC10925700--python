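"""Model parameters: rate/probability conversions, drug-cost construction,
currency handling, and configuration loading.

Every tunable quantity of the cost-effectiveness model lives here as a
:class:`ParameterSpec` (baseline, low, high, sampling family) collected into a
:class:`ModelParameters` bundle.  The sensitivity analyses consume the specs;
the Markov engine consumes the point values.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping

import yaml

__all__ = [
    "ParameterSpec",
    "StatinPrice",
    "StatinPriceTable",
    "TransitionParameters",
    "CostParameters",
    "UtilityParameters",
    "EconSettings",
    "ModelParameters",
    "ConfigError",
    "rate_to_probability",
    "probability_to_rate",
    "apply_relative_risk",
    "adjusted_statin_shares",
    "weighted_statin_daily_cost",
    "annual_drug_and_monitoring_cost",
    "rmb_to_usd",
    "load_parameters",
    "default_parameters",
]

FAMILIES = ("beta", "gamma", "lognormal", "fixed")


class ConfigError(ValueError):
    """Raised when a configuration document is structurally invalid."""


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain model input with its sensitivity range and PSA family."""

    name: str
    baseline: float
    low: float
    high: float
    family: str = "fixed"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(f"{self.name}: unknown family {self.family!r}")
        if not (self.low <= self.baseline <= self.high):
            raise ConfigError(
                f"{self.name}: baseline {self.baseline} outside [{self.low}, {self.high}]"
            )
        if self.family == "beta" and not (0.0 <= self.low and self.high <= 1.0):
            raise ConfigError(f"{self.name}: beta-family values must lie in [0, 1]")
        if self.family == "gamma" and self.low < 0.0:
            raise ConfigError(f"{self.name}: gamma-family values must be >= 0")

    @property
    def varied(self) -> bool:
        return self.high > self.low


# ---------------------------------------------------------------------------
# rate <-> probability conversions

def rate_to_probability(rate: float, t: float = 1.0) -> float:
    """Convert an annual event rate to a transition probability over ``t`` years.

    Uses the exponential-hazard form ``1 - exp(t * ln(1 - rate))``; at t = 1
    this reduces to the identity, matching the convention used to turn the
    observed annual MI incidence into a one-year transition probability.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    if t <= 0:
        raise ValueError(f"t must be positive, got {t}")
    return -math.expm1(t * math.log1p(-rate))


def probability_to_rate(p: float, t: float = 1.0) -> float:
    """Inverse of :func:`rate_to_probability`: the annual rate whose t-year
    probability is ``p``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"t must be positive, got {t}")
    return -math.expm1(math.log1p(-p) / t)


def apply_relative_risk(p: float, rr: float) -> float:
    """Adjust a probability by a relative risk on the rate scale.

    The probability is mapped to a rate, multiplied by ``rr``, and mapped
    back: ``1 - (1 - p)**rr`` for a one-year cycle.  Exact for small p and
    consistent with the rate-based conversion above.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must be in [0, 1), got {p}")
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    return -math.expm1(rr * math.log1p(-p))


# ---------------------------------------------------------------------------
# statin price table

@dataclass(frozen=True)
class StatinPrice:
    drug: str
    per_day_prices: tuple[float, ...]   # RMB per day at the 20 mg-equivalent dose
    unadjusted_pct: float               # % of patients on this statin (may overlap)

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.per_day_prices):
            raise ValueError(f"{self.drug}: negative per-day price")
        if self.unadjusted_pct < 0:
            raise ValueError(f"{self.drug}: negative usage percentage")


@dataclass(frozen=True)
class StatinPriceTable:
    rows: tuple[StatinPrice, ...]

    @classmethod
    def default(cls) -> "StatinPriceTable":
        """Guangdong procurement / list prices for the three statins that
        dominate usage (fluvastatin, at 0.03% usage, is omitted from the
        cost weighting)."""
        return cls(rows=(
            StatinPrice("atorvastatin", (0.4, 0.3, 6.1), 45.41),
            StatinPrice("rosuvastatin", (11.10, 0.40, 3.90), 58.58),
            StatinPrice("simvastatin", (0.11,), 13.22),
        ))


def adjusted_statin_shares(table: StatinPriceTable) -> dict[str, float]:
    """Renormalise overlapping usage percentages to shares summing to one.

    Usage percentages may sum past 100 because patients can take more than
    one statin; each share is ``pct / sum(pct)``.
    """
    if not table.rows:
        raise ValueError("statin price table is empty")
    total = sum(r.unadjusted_pct for r in table.rows)
    if total <= 0:
        raise ValueError("all statin usage percentages are zero")
    return {r.drug: r.unadjusted_pct / total for r in table.rows}


def weighted_statin_daily_cost(
    table: StatinPriceTable, round_averages_to: int | None = 1
) -> float:
    """Usage-share-weighted average daily statin cost (RMB/day).

    Each drug's per-day prices are averaged, the average rounded to
    ``round_averages_to`` decimals (default 1, the precision at which daily
    prices are quoted; pass ``None`` for no rounding), and the rounded
    averages combined with the adjusted usage shares.
    """
    shares = adjusted_statin_shares(table)
    total = 0.0
    for row in table.rows:
        if not row.per_day_prices:
            raise ValueError(f"{row.drug}: no per-day prices")
        avg = sum(row.per_day_prices) / len(row.per_day_prices)
        if round_averages_to is not None:
            avg = round(avg, round_averages_to)
        total += shares[row.drug] * avg
    return total


def rmb_to_usd(v: float, rate: float) -> float:
    """Convert RMB to USD at ``rate`` RMB per USD (rounding is left to the
    presentation layer)."""
    if rate <= 0:
        raise ValueError(f"exchange rate must be positive, got {rate}")
    return v / rate


# ---------------------------------------------------------------------------
# parameter bundles

@dataclass(frozen=True)
class TransitionParameters:
    mi_incidence_statin: float = 0.0234
    rr_mi_inclisiran: float = 0.68
    p_revasc: float = 0.032
    p_recurrence: float = 0.041
    rehab_rate: float = 0.0996
    noncvd_mortality_rep: float = 0.0042   # representative q; scales the life table
    noncvd_mortality_ref: float = 0.0042   # anchor the life table was calibrated to
    mi_mortality_at_ref: float = 0.105     # MI-state death prob at the reference q
    post_mi_mortality: float = 0.021
    mi_mortality_fixed: bool = False
    post_mi_mortality_flat: bool = False
    rr_applies_to_recurrence: bool = True

    @property
    def mi_mortality_multiplier(self) -> float:
        """Multiplier on background mortality in the MI state (baseline 25x)."""
        return self.mi_mortality_at_ref / self.noncvd_mortality_ref

    @property
    def noncvd_scale(self) -> float:
        """Scaling applied to the life table's q(age)."""
        return self.noncvd_mortality_rep / self.noncvd_mortality_ref


@dataclass(frozen=True)
class CostParameters:
    """All costs in RMB (2023 after the CPI factor); USD only at presentation."""

    inclisiran_per_injection: float = 20000.00
    injection_fee: float = 36.00
    statin_daily: float = 3.45
    lab_fee_per_visit: float = 211.00
    mi_hospitalization_annual: float = 30381.30
    revascularization: float = 68625.60
    rehab_first_year: float = 18758.50
    rehab_later_years: float = 10800.00
    exchange_rate_rmb_per_usd: float = 6.7261
    cpi_factor_to_2023: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"cost parameter {f.name} is negative")
        if self.exchange_rate_rmb_per_usd <= 0:
            raise ValueError("exchange rate must be positive")


@dataclass(frozen=True)
class UtilityParameters:
    u_pre_mi: float = 0.84
    u_post_event: float = 0.80
    dec_recurrent_mi: float = 0.06
    dec_revasc: float = 0.07

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"utility parameter {f.name}={v} outside [0, 1]")


@dataclass(frozen=True)
class EconSettings:
    discount_rate: float = 0.05
    gdp_per_capita: float = 85698.00
    wtp_per_qaly: float | None = None      # None -> 3 x GDP per capita
    cycle_length: float = 1.0
    start_age: int = 60
    max_age: int = 100
    dosing_year1_injections: int = 3
    dosing_later_injections: int = 2
    lab_visits_per_year: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ValueError("discount rate must be in [0, 1]")
        if self.start_age >= self.max_age:
            raise ValueError("start_age must be below max_age")

    @property
    def wtp(self) -> float:
        return 3.0 * self.gdp_per_capita if self.wtp_per_qaly is None else self.wtp_per_qaly


def annual_drug_and_monitoring_cost(
    arm: str, year_index: int, costs: CostParameters, settings: EconSettings
) -> float:
    """Annual drug plus lipid-monitoring cost (RMB) for one model year.

    Both arms take daily statins (combination therapy) and attend lab visits;
    the inclisiran arm additionally pays per-injection drug and injection-fee
    costs, with three injections in year 1 (day 1, day 90, day 270) and two
    per year thereafter.
    """
    if arm not in ("statin", "inclisiran"):
        raise ValueError(f"unknown arm {arm!r}")
    if year_index < 1:
        raise ValueError(f"year_index must be >= 1, got {year_index}")
    total = costs.statin_daily * 365.0 + settings.lab_visits_per_year * costs.lab_fee_per_visit
    if arm == "inclisiran":
        n_inj = (
            settings.dosing_year1_injections
            if year_index == 1
            else settings.dosing_later_injections
        )
        total += n_inj * (costs.inclisiran_per_injection + costs.injection_fee)
    return total


# mapping of spec name -> bundle section for overrides
_SECTION_OF = {
    "mi_incidence_statin": "transitions",
    "rr_mi_inclisiran": "transitions",
    "p_revasc": "transitions",
    "p_recurrence": "transitions",
    "rehab_rate": "transitions",
    "noncvd_mortality_rep": "transitions",
    "mi_mortality_at_ref": "transitions",
    "post_mi_mortality": "transitions",
    "inclisiran_per_injection": "costs",
    "injection_fee": "costs",
    "statin_daily": "costs",
    "lab_fee_per_visit": "costs",
    "mi_hospitalization_annual": "costs",
    "revascularization": "costs",
    "rehab_first_year": "costs",
    "rehab_later_years": "costs",
    "u_pre_mi": "utilities",
    "u_post_event": "utilities",
    "dec_recurrent_mi": "utilities",
    "dec_revasc": "utilities",
    "discount_rate": "settings",
}


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter bundle: point values per section plus the uncertainty
    specs consumed by the sensitivity analyses."""

    transitions: TransitionParameters = field(default_factory=TransitionParameters)
    costs: CostParameters = field(default_factory=CostParameters)
    utilities: UtilityParameters = field(default_factory=UtilityParameters)
    settings: EconSettings = field(default_factory=EconSettings)
    specs: Mapping[str, ParameterSpec] = field(default_factory=dict)
    psa_seed: int = 20240226
    n_psa: int = 1000
    range_to_sd_divisor: float = 3.92

    def with_overrides(self, overrides: Mapping[str, float]) -> "ModelParameters":
        """Return a copy with named parameters replaced by new point values.

        Names follow the spec names of ``self.specs`` / the config file
        sections; unknown names raise ``KeyError``.  The overridden
        parameter's uncertainty spec moves with it: its bounds are rescaled
        proportionally to the new baseline, so a price-scenario bundle
        samples around the scenario price in the PSA.
        """
        by_section: dict[str, dict[str, float]] = {}
        new_specs = dict(self.specs)
        for name, value in overrides.items():
            section = _SECTION_OF.get(name)
            if section is None:
                raise KeyError(f"unknown parameter {name!r}")
            value = float(value)
            by_section.setdefault(section, {})[name] = value
            old = new_specs.get(name)
            if old is not None:
                if old.baseline > 0 and value > 0:
                    ratio = value / old.baseline
                    low, high = old.low * ratio, old.high * ratio
                    if old.family == "beta":
                        high = min(high, 1.0)
                    new_specs[name] = ParameterSpec(name, value, min(low, value),
                                                    max(high, value), old.family)
                else:
                    new_specs[name] = ParameterSpec(name, value, value, value, "fixed")
        out = dataclasses.replace(self, specs=new_specs)
        for section, kv in by_section.items():
            out = dataclasses.replace(
                out, **{section: dataclasses.replace(getattr(out, section), **kv)}
            )
        return out


# ---------------------------------------------------------------------------
# configuration loading

_SECTIONS = ("settings", "transitions", "costs", "utilities")
_PLAIN_KEYS = {
    "settings": {
        "start_age", "max_age", "cycle_length", "gdp_per_capita", "wtp_per_qaly",
        "dosing_year1_injections", "dosing_later_injections", "lab_visits_per_year",
    },
    "transitions": {
        "noncvd_mortality_ref", "mi_mortality_fixed", "post_mi_mortality_flat",
        "rr_applies_to_recurrence",
    },
    "costs": {"exchange_rate_rmb_per_usd", "cpi_factor_to_2023"},
    "utilities": set(),
}


def _parse_spec(name: str, raw: Any, errors: list[str]) -> ParameterSpec | None:
    if isinstance(raw, (int, float)):
        v = float(raw)
        return ParameterSpec(name, v, v, v, "fixed")
    if not isinstance(raw, dict) or "baseline" not in raw:
        errors.append(f"{name}: expected a number or a mapping with 'baseline'")
        return None
    unknown = set(raw) - {"baseline", "low", "high", "family"}
    if unknown:
        errors.append(f"{name}: unknown keys {sorted(unknown)}")
        return None
    baseline = float(raw["baseline"])
    family = raw.get("family", "fixed")
    low, high = raw.get("low"), raw.get("high")
    if (low is None) != (high is None):
        errors.append(f"{name}: low and high must be given together")
        return None
    if low is None:
        if family == "fixed":
            low = high = baseline
        else:
            # +/-20% default when no explicit bounds are printed
            low, high = 0.8 * baseline, 1.2 * baseline
            if family == "beta":
                high = min(high, 1.0)
    try:
        return ParameterSpec(name, baseline, float(low), float(high), family)
    except ConfigError as exc:
        errors.append(str(exc))
        return None


def _load_yaml(source: Any) -> dict:
    if isinstance(source, dict):
        return source
    if hasattr(source, "read"):
        doc = yaml.safe_load(source.read())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("configuration document is empty or not a mapping")
    return doc


def load_parameters(source: Any) -> ModelParameters:
    """Build a :class:`ModelParameters` bundle from a YAML file, an open
    stream, or an equivalent nested dict.

    Validation is strict: unknown sections or keys, missing baselines, and
    baselines outside their bounds are all reported together by key name.
    """
    doc = _load_yaml(source)
    errors: list[str] = []
    unknown_sections = set(doc) - set(_SECTIONS) - {"sensitivity"}
    if unknown_sections:
        errors.append(f"unknown sections {sorted(unknown_sections)}")

    specs: dict[str, ParameterSpec] = {}
    plain: dict[str, dict[str, Any]] = {s: {} for s in _SECTIONS}
    for section in _SECTIONS:
        content = doc.get(section, {})
        if not isinstance(content, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key, raw in content.items():
            if key in _PLAIN_KEYS[section]:
                plain[section][key] = raw
            elif key in _SECTION_OF and _SECTION_OF[key] == section:
                spec = _parse_spec(key, raw, errors)
                if spec is not None:
                    specs[key] = spec
            else:
                errors.append(f"{section}.{key}: unknown key")
    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))

    def point(name: str, default: float) -> float:
        return specs[name].baseline if name in specs else default

    transitions = TransitionParameters(
        mi_incidence_statin=point("mi_incidence_statin", 0.0234),
        rr_mi_inclisiran=point("rr_mi_inclisiran", 0.68),
        p_revasc=point("p_revasc", 0.032),
        p_recurrence=point("p_recurrence", 0.041),
        rehab_rate=point("rehab_rate", 0.0996),
        noncvd_mortality_rep=point("noncvd_mortality_rep", 0.0042),
        mi_mortality_at_ref=point("mi_mortality_at_ref", 0.105),
        post_mi_mortality=point("post_mi_mortality", 0.021),
        noncvd_mortality_ref=float(plain["transitions"].get("noncvd_mortality_ref", 0.0042)),
        mi_mortality_fixed=bool(plain["transitions"].get("mi_mortality_fixed", False)),
        post_mi_mortality_flat=bool(plain["transitions"].get("post_mi_mortality_flat", False)),
        rr_applies_to_recurrence=bool(plain["transitions"].get("rr_applies_to_recurrence", True)),
    )
    cpi = float(plain["costs"].get("cpi_factor_to_2023", 1.0))
    if cpi != 1.0:
        # inflate cost specs (baseline and bounds) to the analysis year
        for name in list(specs):
            if _SECTION_OF.get(name) == "costs":
                sp = specs[name]
                specs[name] = ParameterSpec(
                    sp.name, cpi * sp.baseline, cpi * sp.low, cpi * sp.high, sp.family
                )

    def cost_point(name: str, default: float) -> float:
        return specs[name].baseline if name in specs else cpi * default

    costs = CostParameters(
        inclisiran_per_injection=cost_point("inclisiran_per_injection", 20000.00),
        injection_fee=cost_point("injection_fee", 36.00),
        statin_daily=cost_point("statin_daily", 3.45),
        lab_fee_per_visit=cost_point("lab_fee_per_visit", 211.00),
        mi_hospitalization_annual=cost_point("mi_hospitalization_annual", 30381.30),
        revascularization=cost_point("revascularization", 68625.60),
        rehab_first_year=cost_point("rehab_first_year", 18758.50),
        rehab_later_years=cost_point("rehab_later_years", 10800.00),
        exchange_rate_rmb_per_usd=float(plain["costs"].get("exchange_rate_rmb_per_usd", 6.7261)),
        cpi_factor_to_2023=cpi,
    )
    utilities = UtilityParameters(
        u_pre_mi=point("u_pre_mi", 0.84),
        u_post_event=point("u_post_event", 0.80),
        dec_recurrent_mi=point("dec_recurrent_mi", 0.06),
        dec_revasc=point("dec_revasc", 0.07),
    )
    s = plain["settings"]
    wtp = s.get("wtp_per_qaly")
    settings = EconSettings(
        discount_rate=point("discount_rate", 0.05),
        gdp_per_capita=float(s.get("gdp_per_capita", 85698.00)),
        wtp_per_qaly=None if wtp is None else float(wtp),
        cycle_length=float(s.get("cycle_length", 1.0)),
        start_age=int(s.get("start_age", 60)),
        max_age=int(s.get("max_age", 100)),
        dosing_year1_injections=int(s.get("dosing_year1_injections", 3)),
        dosing_later_injections=int(s.get("dosing_later_injections", 2)),
        lab_visits_per_year=int(s.get("lab_visits_per_year", 2)),
    )
    sens = doc.get("sensitivity", {}) or {}
    return ModelParameters(
        transitions=transitions,
        costs=costs,
        utilities=utilities,
        settings=settings,
        specs=specs,
        psa_seed=int(sens.get("seed", 20240226)),
        n_psa=int(sens.get("n_psa", 1000)),
        range_to_sd_divisor=float(sens.get("range_to_sd_divisor", 3.92)),
    )


def default_parameters() -> ModelParameters:
    """The shipped default configuration (all printed baseline values)."""
    with resources.files("lipidce.data").joinpath("default_config.yaml").open(
        "r", encoding="utf-8"
    ) as fh:
        return load_parameters(fh)
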