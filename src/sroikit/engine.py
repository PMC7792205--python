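"""SROI valuation mathematics.

The per-outcome annual benefit model is

    population x incidence x risk_reduction x unit_value x retention

where retention = (1-deadweight)(1-displacement)(1-attribution) is the SROI
impact-adjustment factor. Benefit streams decay geometrically with the
annual drop-off rate from year 2 onward (year 1 pays the full annual
value), and streams are discounted end-of-period:

    NPV = sum_t  v_t / (1 + r)^t,   t = 1..duration

The SROI ratio is (benefit basis - investment) / investment. Reported
(integer) ratios truncate toward zero; reported money values round half-up
to the nearest whole AUD.

``evaluate`` offers two modes. ``simple`` uses the annual benefit total
(or the scenario's ``total_benefit_override``) as the ratio basis — the
mode that reproduces the published Calvary headline ratio of 55:1.
``npv`` builds a per-outcome stream over each outcome's duration, applies
drop-off and discounting, and uses the summed NPV as the basis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import ImpactAdjustments, OutcomeSpec, Scenario

__all__ = [
    "BenefitStream",
    "SROIResult",
    "round_money",
    "annual_benefit",
    "benefit_stream",
    "npv",
    "total_annual_benefit",
    "benefit_basis",
    "sroi_ratio",
    "payback_months",
    "evaluate",
]


def round_money(x: float) -> int:
    """Round a non-negative money amount half-up to whole AUD."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BenefitStream:
    """Per-year benefit values for one outcome, years t = 1..duration."""

    outcome_name: str
    yearly_values: tuple[float, ...]

    @property
    def duration_years(self) -> int:
        return len(self.yearly_values)


@dataclass(frozen=True)
class SROIResult:
    """Full result of an SROI evaluation.

    ``ratio_raw`` keeps full precision; ``ratio_reported`` truncates toward
    zero (the convention that reproduces every published integer ratio in
    the Calvary case). ``total_annual_benefit`` is always the computed
    outcome sum; ``benefit_basis`` is whatever basis the declared mode used
    for the ratio (the override, when present in simple mode).
    """

    mode: str
    per_outcome_annual: dict[str, float]
    total_annual_benefit: float
    npv_total: float
    benefit_basis: float
    investment: float
    ratio_raw: float
    ratio_reported: int
    net_yield: float
    payback_months: float

    def to_dict(self) -> dict:
        """JSON-safe dict; money to 2 decimals, ratios raw + reported."""
        return {
            "mode": self.mode,
            "per_outcome_annual": {
                k: round(v, 2) for k, v in self.per_outcome_annual.items()
            },
            "total_annual_benefit": round(self.total_annual_benefit, 2),
            "npv_total": round(self.npv_total, 2),
            "benefit_basis": round(self.benefit_basis, 2),
            "investment": round(self.investment, 2),
            "ratio_raw": self.ratio_raw,
            "ratio_reported": self.ratio_reported,
            "net_yield": round(self.net_yield, 2),
            "payback_months": self.payback_months,
        }

    def to_rows(self) -> list[dict]:
        """Long-form rows (one per outcome plus summary lines) for CSV."""
        rows = [
            {"field": f"outcome:{name}", "value": round(v, 2)}
            for name, v in self.per_outcome_annual.items()
        ]
        for key in (
            "total_annual_benefit",
            "npv_total",
            "benefit_basis",
            "investment",
            "net_yield",
        ):
            rows.append({"field": key, "value": round(getattr(self, key), 2)})
        rows.append({"field": "ratio_raw", "value": self.ratio_raw})
        rows.append({"field": "ratio_reported", "value": self.ratio_reported})
        rows.append({"field": "payback_months", "value": self.payback_months})
        return rows


def annual_benefit(
    o: OutcomeSpec,
    population: int,
    adj: ImpactAdjustments,
    breastfeeding_rate: float = 1.0,
) -> float:
    """Full-precision annual benefit of one outcome line, in AUD/year.

    ``breastfeeding_rate`` defaults to 1 because the published Calvary rows
    value the full birth cohort; pass the scenario's rate only when
    ``apply_breastfeeding_rate`` is set.
    """
    return (
        population
        * breastfeeding_rate
        * o.incidence
        * o.risk_reduction
        * o.unit_value
        * adj.retention
    )


def benefit_stream(annual: float, duration_years: int, drop_off: float) -> BenefitStream:
    """Geometrically decaying stream: v_t = annual * (1 - drop_off)^(t-1)."""
    if duration_years < 1:
        raise ValueError(f"duration_years must be >= 1, got {duration_years}")
    keep = 1.0 - drop_off
    values = tuple(annual * keep ** (t - 1) for t in range(1, duration_years + 1))
    return BenefitStream(outcome_name="", yearly_values=values)


def npv(stream: BenefitStream, discount_rate: float) -> float:
    """End-of-period discounted present value: sum v_t (1+r)^(-t)."""
    if discount_rate < 0:
        raise ValueError("discount_rate must be >= 0")
    r = 1.0 + discount_rate
    return sum(v / r**t for t, v in enumerate(stream.yearly_values, start=1))


def _per_outcome(s: Scenario) -> dict[str, float]:
    bf = s.breastfeeding_rate if s.apply_breastfeeding_rate else 1.0
    return {
        o.name: annual_benefit(o, s.population, s.adjustments, bf)
        for o in s.outcomes
    }


def total_annual_benefit(s: Scenario) -> float:
    """Sum of the engine-computed annual benefits over all outcomes."""
    return sum(_per_outcome(s).values())


def benefit_basis(s: Scenario) -> float:
    """Annual benefit basis for ratio work: the override when present."""
    if s.total_benefit_override is not None:
        return s.total_benefit_override
    return total_annual_benefit(s)


def sroi_ratio(benefit: float, investment: float) -> tuple[float, int]:
    """(raw, reported) SROI ratio: (benefit - investment) / investment.

    The reported value truncates toward zero.
    """
    if investment <= 0:
        raise ValueError("investment must be > 0")
    raw = (benefit - investment) / investment
    return raw, math.trunc(raw)


def payback_months(investment: float, annual_benefit_total: float) -> float:
    """Months until cumulative benefit equals the investment, assuming
    uniform within-year accrual: 12 * investment / annual benefit."""
    if annual_benefit_total <= 0:
        raise ValueError("annual benefit must be > 0")
    return 12.0 * investment / annual_benefit_total


def evaluate(s: Scenario, mode: str = "simple") -> SROIResult:
    """Run the full valuation.

    simple: ratio basis = annual benefit total (override if present).
    npv:    ratio basis = summed NPV of per-outcome drop-off-decayed,
            discounted streams (the override, an annual figure, does not
            apply here).

    Payback always uses the annual basis.
    """
    if mode not in ("simple", "npv"):
        raise ValueError(f"mode must be 'simple' or 'npv', got {mode!r}")
    per = _per_outcome(s)
    total = sum(per.values())
    npv_total = sum(
        npv(benefit_stream(per[o.name], o.duration_years, s.adjustments.drop_off),
            s.discount_rate)
        for o in s.outcomes
    )
    annual_basis = s.total_benefit_override if s.total_benefit_override is not None else total
    basis = annual_basis if mode == "simple" else npv_total
    raw, reported = sroi_ratio(basis, s.investment)
    return SROIResult(
        mode=mode,
        per_outcome_annual=per,
        total_annual_benefit=total,
        npv_total=npv_total,
        benefit_basis=basis,
        investment=s.investment,
        ratio_raw=raw,
        ratio_reported=reported,
        net_yield=basis - s.investment,
        payback_months=payback_months(s.investment, annual_basis),
    )
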