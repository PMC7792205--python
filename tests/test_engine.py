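"""Valuation engine: row values, streams, NPV, ratio, payback, evaluate."""

import dataclasses
import math
import random

import pytest

from sroikit import (
    ImpactAdjustments,
    OutcomeSpec,
    annual_benefit,
    benefit_stream,
    calvary_fixture,
    evaluate,
    npv,
    payback_months,
    round_money,
    sroi_ratio,
    total_annual_benefit,
)
from sroikit.engine import BenefitStream

CALVARY_ADJ = ImpactAdjustments(0.05, 0.20, 0.25, 0.20)

# Published per-outcome annual values that the declared formula
# pop x incidence x risk_reduction x proxy x (1-dw)(1-disp)(1-attr)
# reproduces exactly (to the nearest AUD).
RECONCILABLE_ROWS = [
    ("Reduce risk of diarrhea", 3_004),
    ("Reduce risk of respiratory infection", 41_138),
    ("Reduce risk of acute otitis media", 36_397),
    ("Higher IQ", 9),
    ("Reduce risk of type 1 diabetes", 118),
    ("Reduce risk of Sudden Infant Death Syndrome (SIDS)", 612_091),
    ("Reduce risk of hypertension", 4_679),
]

# Rows whose published values do not follow from their published inputs;
# the engine reports its own arithmetic and the published value is carried
# separately as printed_value.
DISCREPANT_ROWS = [
    "Reduce risk of necrotizing enterocolitis",
    "Reduce risk of obesity",
    "Reduce risk of type 2 diabetes",
    "Reduce risk of breast cancer",
    "Reduce risk of cardiovascular disease",
    "Not buying formula",
    "Reduce risk of ovarian cancer",
]


class TestAnnualBenefit:
    @pytest.mark.parametrize("name,expected", RECONCILABLE_ROWS)
    def test_reproduces_published_rows(self, calvary, name, expected):
        o = calvary.outcome(name)
        value = annual_benefit(o, calvary.population, calvary.adjustments)
        assert round_money(value) == expected
        assert round_money(value) == round_money(o.printed_value)

    @pytest.mark.parametrize("name", DISCREPANT_ROWS)
    def test_discrepant_rows_are_documented_not_matched(self, calvary, name):
        o = calvary.outcome(name)
        value = annual_benefit(o, calvary.population, calvary.adjustments)
        assert round_money(value) != round_money(o.printed_value)

    def test_zero_incidence_gives_zero(self):
        o = OutcomeSpec("x", "infant", 0.0, 0.5, 1000.0, 3)
        assert annual_benefit(o, 1000, CALVARY_ADJ) == 0.0

    def test_unit_retention(self):
        o = OutcomeSpec("x", "infant", 0.1, 0.5, 10.0, 3)
        assert annual_benefit(o, 100, ImpactAdjustments(0, 0, 0, 0)) == pytest.approx(50.0)

    def test_order_invariance_of_total(self, calvary):
        shuffled = list(calvary.outcomes)
        random.Random(3).shuffle(shuffled)
        s2 = dataclasses.replace(calvary, outcomes=tuple(shuffled))
        assert total_annual_benefit(s2) == pytest.approx(
            total_annual_benefit(calvary), rel=1e-12
        )

    def test_linearity_in_unit_values(self, calvary):
        k = 3.7
        scaled = dataclasses.replace(
            calvary,
            outcomes=tuple(
                dataclasses.replace(o, unit_value=o.unit_value * k)
                for o in calvary.outcomes
            ),
        )
        assert total_annual_benefit(scaled) == pytest.approx(
            k * total_annual_benefit(calvary), rel=1e-12
        )


class TestBenefitStream:
    def test_geometric_decay(self):
        stream = benefit_stream(100.0, 3, 0.2)
        assert stream.yearly_values == pytest.approx((100.0, 80.0, 64.0), rel=1e-12)

    def test_zero_drop_off_constant(self):
        assert benefit_stream(42.0, 4, 0.0).yearly_values == (42.0,) * 4

    def test_first_year_pays_full_annual(self):
        assert benefit_stream(612_091.08, 30, 0.2).yearly_values[0] == 612_091.08

    def test_year_30_by_direct_exponentiation(self):
        stream = benefit_stream(612_091.08, 30, 0.2)
        assert stream.yearly_values[-1] == pytest.approx(
            612_091.08 * 0.8**29, rel=1e-12
        )

    def test_non_increasing(self):
        v = benefit_stream(100.0, 10, 0.35).yearly_values
        assert all(a >= b for a, b in zip(v, v[1:]))

    def test_duration_below_one_rejected(self):
        with pytest.raises(ValueError):
            benefit_stream(100.0, 0, 0.2)


class TestNPV:
    def test_undiscounted_sum(self):
        assert npv(BenefitStream("x", (100.0, 80.0, 64.0)), 0.0) == pytest.approx(244.0)

    def test_single_period_identity(self):
        assert npv(BenefitStream("x", (104.0,)), 0.04) == pytest.approx(100.0)

    @pytest.mark.parametrize("annual,rate,years", [
        (100.0, 0.04, 15),
        (612_091.08, 0.04, 30),
        (1.0, 0.12, 2),
        (5000.0, 0.001, 50),
    ])
    def test_constant_stream_matches_annuity_closed_form(self, annual, rate, years):
        stream = BenefitStream("x", (annual,) * years)
        closed = annual * (1 - (1 + rate) ** (-years)) / rate
        assert npv(stream, rate) == pytest.approx(closed, rel=1e-9)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            npv(BenefitStream("x", (1.0,)), -0.01)


class TestRatioAndPayback:
    def test_published_headline(self):
        raw, reported = sroi_ratio(1_375_050.0, 24_433.80)
        assert reported == 55
        assert raw == pytest.approx(55.2766, abs=1e-4)

    @pytest.mark.parametrize("basis,inv,expected", [(100.0, 100.0, (0.0, 0)),
                                                    (200.0, 100.0, (1.0, 1))])
    def test_break_even_and_doubling(self, basis, inv, expected):
        raw, reported = sroi_ratio(basis, inv)
        assert (raw, reported) == expected

    def test_reported_truncates_toward_zero(self):
        assert sroi_ratio(56.9, 1.0)[1] == 55
        assert sroi_ratio(0.5, 1.0)[1] == 0  # raw -0.5 truncates to 0

    def test_nonpositive_investment_rejected(self):
        with pytest.raises(ValueError):
            sroi_ratio(100.0, 0.0)

    @pytest.mark.parametrize("inv,benefit,expected", [
        (24_433.80, 1_375_050.0, 12 * 24_433.80 / 1_375_050.0),
        (100.0, 100.0, 12.0),
        (100.0, 200.0, 6.0),
    ])
    def test_payback_uniform_accrual(self, inv, benefit, expected):
        assert payback_months(inv, benefit) == pytest.approx(expected)

    def test_payback_needs_positive_benefit(self):
        with pytest.raises(ValueError):
            payback_months(100.0, 0.0)


class TestEvaluate:
    def test_fixture_simple_mode_headline(self, calvary):
        res = evaluate(calvary, "simple")
        assert res.ratio_reported == 55
        assert res.benefit_basis == 1_375_050.0
        assert len(res.per_outcome_annual) == 14
        assert res.payback_months == pytest.approx(12 * 24_433.80 / 1_375_050.0)

    def test_fixture_computed_sum_exposed_alongside_override(self, calvary):
        res = evaluate(calvary, "simple")
        assert res.total_annual_benefit == pytest.approx(
            sum(res.per_outcome_annual.values()), rel=1e-12
        )
        assert res.total_annual_benefit != res.benefit_basis

    def test_degenerate_modes_agree(self):
        s = dataclasses.replace(
            calvary_fixture(),
            outcomes=(OutcomeSpec("only", "infant", 0.1, 0.5, 1000.0, 1),),
            adjustments=ImpactAdjustments(0.0, 0.0, 0.0, 0.0),
            discount_rate=0.0,
            total_benefit_override=None,
        )
        simple = evaluate(s, "simple")
        by_npv = evaluate(s, "npv")
        assert simple.benefit_basis == pytest.approx(by_npv.benefit_basis, rel=1e-12)
        assert simple.ratio_raw == pytest.approx(by_npv.ratio_raw, rel=1e-12)

    def test_npv_basis_equals_brute_force_accumulation(self, calvary):
        res = evaluate(calvary, "npv")
        brute = 0.0
        for o in calvary.outcomes:
            annual = res.per_outcome_annual[o.name]
            for t in range(1, o.duration_years + 1):
                brute += (
                    annual
                    * (1 - calvary.adjustments.drop_off) ** (t - 1)
                    / (1 + calvary.discount_rate) ** t
                )
        assert res.npv_total == pytest.approx(brute, rel=1e-9)
        assert res.benefit_basis == res.npv_total

    def test_ratio_strictly_decreasing_in_each_adjustment(self, calvary):
        base = dataclasses.replace(calvary, total_benefit_override=None)
        r0 = evaluate(base, "simple").ratio_raw
        for fname in ("deadweight", "displacement", "attribution"):
            bumped = dataclasses.replace(
                base,
                adjustments=dataclasses.replace(
                    base.adjustments, **{fname: getattr(base.adjustments, fname) + 0.1}
                ),
            )
            assert evaluate(bumped, "simple").ratio_raw < r0

    def test_unknown_mode_rejected(self, calvary):
        with pytest.raises(ValueError):
            evaluate(calvary, "fancy")

    def test_result_serialization_round_numbers(self, calvary):
        d = evaluate(calvary, "simple").to_dict()
        assert d["investment"] == 24_433.80
        assert d["ratio_reported"] == 55
        assert len(d["per_outcome_annual"]) == 14


def test_breastfeeding_rate_not_applied_by_default(calvary):
    sids = calvary.outcome("Reduce risk of Sudden Infant Death Syndrome (SIDS)")
    full = annual_benefit(sids, calvary.population, calvary.adjustments)
    assert round_money(full) == 612_091  # full cohort of 1000, not 970

    applied = dataclasses.replace(calvary, apply_breastfeeding_rate=True)
    res = evaluate(applied, "simple")
    assert res.per_outcome_annual[sids.name] == pytest.approx(0.97 * full, rel=1e-12)
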