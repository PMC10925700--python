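"""Parameter registry: conversions, statin-cost construction, config loading."""
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lipidce.params import (
    ConfigError,
    ParameterSpec,
    StatinPrice,
    StatinPriceTable,
    adjusted_statin_shares,
    annual_drug_and_monitoring_cost,
    apply_relative_risk,
    default_parameters,
    load_parameters,
    probability_to_rate,
    rate_to_probability,
    rmb_to_usd,
    weighted_statin_daily_cost,
)


class TestRateProbability:
    @pytest.mark.parametrize(
        "rate,t,expected",
        [
            (0.0234, 1.0, 0.0234),                      # annual MI incidence: identity at t=1
            (0.0, 1.0, 0.0),
            (0.0234, 0.5, 1 - math.exp(0.5 * math.log(1 - 0.0234))),
        ],
    )
    def test_examples(self, rate, t, expected):
        assert rate_to_probability(rate, t) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p,t,expected", [(0.0234, 1, 0.0234), (0.0, 1, 0.0), (0.5, 2, 1 - 0.5**0.5)])
    def test_inverse_examples(self, p, t, expected):
        assert probability_to_rate(p, t) == pytest.approx(expected, abs=1e-12)

    @given(
        rate=st.floats(0.0, 0.99),
        t=st.sampled_from([0.25, 0.5, 1.0, 2.0]),
    )
    def test_roundtrip(self, rate, t):
        p = rate_to_probability(rate, t)
        assert 0.0 <= p < 1.0
        assert rate_to_probability(probability_to_rate(p, t), t) == pytest.approx(p, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError, match="rate"):
            rate_to_probability(bad)
        with pytest.raises(ValueError, match="probability"):
            probability_to_rate(bad)


class TestRelativeRisk:
    def test_examples(self):
        assert apply_relative_risk(0.0234, 1.0) == pytest.approx(0.0234, abs=1e-15)
        assert apply_relative_risk(0.0234, 0.68) == pytest.approx(1 - (1 - 0.0234) ** 0.68, abs=1e-15)
        assert apply_relative_risk(0.0, 0.68) == 0.0

    @given(
        p=st.floats(0.001, 0.99),
        rr1=st.floats(0.1, 2.0),
        rr2=st.floats(0.1, 2.0),
    )
    def test_monotone_in_rr(self, p, rr1, rr2):
        lo, hi = sorted([rr1, rr2])
        assert apply_relative_risk(p, lo) <= apply_relative_risk(p, hi)

    @given(p=st.floats(0.001, 0.99))
    def test_protective_rr_strictly_decreases(self, p):
        assert apply_relative_risk(p, 0.68) < p

    def test_rejects_nonpositive_rr(self):
        with pytest.raises(ValueError):
            apply_relative_risk(0.1, 0.0)


class TestStatinCosts:
    def test_published_shares(self):
        shares = adjusted_statin_shares(StatinPriceTable.default())
        assert shares["atorvastatin"] == pytest.approx(0.3874, abs=5e-5)
        assert shares["rosuvastatin"] == pytest.approx(0.4998, abs=5e-5)
        assert shares["simvastatin"] == pytest.approx(0.1128, abs=5e-5)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_drug_and_symmetry(self):
        one = StatinPriceTable((StatinPrice("only", (5.0,), 100.0),))
        assert adjusted_statin_shares(one) == {"only": 1.0}
        two = StatinPriceTable(
            (StatinPrice("a", (2.0,), 30.0), StatinPrice("b", (4.0,), 30.0))
        )
        assert adjusted_statin_shares(two) == {"a": 0.5, "b": 0.5}
        assert weighted_statin_daily_cost(two) == pytest.approx(3.0)

    @given(scale=st.floats(0.01, 100.0))
    def test_shares_invariant_under_rescaling(self, scale):
        base = StatinPriceTable.default()
        scaled = StatinPriceTable(
            tuple(
                StatinPrice(r.drug, r.per_day_prices, r.unadjusted_pct * scale)
                for r in base.rows
            )
        )
        for d, s in adjusted_statin_shares(base).items():
            assert adjusted_statin_shares(scaled)[d] == pytest.approx(s, rel=1e-9)

    def test_zero_percentages_rejected(self):
        table = StatinPriceTable((StatinPrice("a", (1.0,), 0.0),))
        with pytest.raises(ValueError, match="zero"):
            adjusted_statin_shares(table)

    def test_published_weighted_cost(self):
        # per-drug daily averages round to 2.3 / 5.1 / 0.1; weighted total 3.45
        table = StatinPriceTable.default()
        avg = {r.drug: sum(r.per_day_prices) / len(r.per_day_prices) for r in table.rows}
        assert round(avg["atorvastatin"], 1) == 2.3
        assert round(avg["rosuvastatin"], 1) == 5.1
        assert round(weighted_statin_daily_cost(table), 2) == 3.45

    def test_exact_mode_differs_only_by_rounding(self):
        table = StatinPriceTable.default()
        exact = weighted_statin_daily_cost(table, round_averages_to=None)
        assert exact == pytest.approx(3.4561, abs=5e-5)


class TestAnnualCost:
    def test_statin_arm(self, params):
        c = annual_drug_and_monitoring_cost("statin", 1, params.costs, params.settings)
        assert c == pytest.approx(3.45 * 365 + 2 * 211.0)   # 1,681.25
        # identical in later years
        assert annual_drug_and_monitoring_cost("statin", 7, params.costs, params.settings) == c

    def test_inclisiran_dosing_schedule(self, params):
        statin = annual_drug_and_monitoring_cost("statin", 1, params.costs, params.settings)
        y1 = annual_drug_and_monitoring_cost("inclisiran", 1, params.costs, params.settings)
        y2 = annual_drug_and_monitoring_cost("inclisiran", 2, params.costs, params.settings)
        assert y1 - statin == pytest.approx(3 * 20036.0)
        assert y2 - statin == pytest.approx(2 * 20036.0)

    def test_degenerate_zero_costs(self, params):
        import dataclasses

        zero = dataclasses.replace(
            params.costs,
            inclisiran_per_injection=0.0,
            injection_fee=0.0,
            statin_daily=0.0,
            lab_fee_per_visit=0.0,
        )
        assert annual_drug_and_monitoring_cost("inclisiran", 1, zero, params.settings) == 0.0

    def test_bad_inputs(self, params):
        with pytest.raises(ValueError):
            annual_drug_and_monitoring_cost("statin", 0, params.costs, params.settings)
        with pytest.raises(ValueError):
            annual_drug_and_monitoring_cost("aspirin", 1, params.costs, params.settings)


class TestCurrency:
    def test_published_conversions(self):
        assert round(rmb_to_usd(20000.00, 6.7261), 2) == 2973.49
        assert round(rmb_to_usd(672.61, 6.7261), 2) == 100.00
        assert rmb_to_usd(0.0, 6.7261) == 0.0

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            rmb_to_usd(1.0, 0.0)


class TestConfigLoading:
    def test_default_matches_published_baselines(self, params):
        tr, c, u, s = params.transitions, params.costs, params.utilities, params.settings
        assert tr.mi_incidence_statin == 0.0234
        assert tr.rr_mi_inclisiran == 0.68
        assert tr.p_revasc == 0.032
        assert tr.p_recurrence == 0.041
        assert tr.rehab_rate == 0.0996
        assert tr.noncvd_mortality_rep == 0.0042
        assert tr.mi_mortality_multiplier == pytest.approx(25.0)
        assert tr.post_mi_mortality == 0.021
        assert c.inclisiran_per_injection == 20000.00
        assert c.injection_fee == 36.00
        assert c.statin_daily == 3.45
        assert c.lab_fee_per_visit == 211.00
        assert c.mi_hospitalization_annual == 30381.30
        assert c.revascularization == 68625.60
        assert c.rehab_first_year == 18758.50
        assert c.rehab_later_years == 10800.00
        assert u.u_pre_mi == 0.84 and u.u_post_event == 0.80
        assert u.dec_recurrent_mi == 0.06 and u.dec_revasc == 0.07
        assert s.discount_rate == 0.05
        assert s.wtp == pytest.approx(3 * 85698.00)

    def test_missing_bounds_default_to_20pct(self, params):
        spec = params.specs["dec_recurrent_mi"]
        assert spec.low == pytest.approx(0.8 * 0.06)
        assert spec.high == pytest.approx(1.2 * 0.06)

    def test_empty_document_rejected(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        with pytest.raises(ConfigError):
            load_parameters(path)

    def test_baseline_outside_bounds_rejected(self):
        doc = {"transitions": {"mi_incidence_statin": {"baseline": 0.5, "low": 0.01, "high": 0.03, "family": "beta"}}}
        with pytest.raises(ConfigError, match="mi_incidence_statin"):
            load_parameters(doc)

    def test_unknown_keys_named_in_error(self):
        with pytest.raises(ConfigError, match="not_a_cost"):
            load_parameters({"costs": {"not_a_cost": 1.0}})

    def test_beta_family_range_enforced(self):
        with pytest.raises(ConfigError, match=r"\[0, 1\]"):
            ParameterSpec("x", 0.5, 0.1, 1.5, "beta")

    def test_override_moves_point_and_spec(self, params):
        p2 = params.with_overrides({"inclisiran_per_injection": 2500.0})
        assert p2.costs.inclisiran_per_injection == 2500.0
        spec = p2.specs["inclisiran_per_injection"]
        assert spec.baseline == 2500.0
        assert spec.low == pytest.approx(2000.0) and spec.high == pytest.approx(3000.0)
        with pytest.raises(KeyError):
            params.with_overrides({"nonexistent": 1.0})

    def test_default_config_reload_is_stable(self, params):
        assert default_parameters().transitions == params.transitions
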