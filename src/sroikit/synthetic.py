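"""Seeded generator of valid random SROI scenarios.

Used by property-based tests and by anyone who wants structurally
realistic inputs without case-study data. Defaults mirror the shape of the
Calvary BFHI tables: a birth cohort in the hundreds-to-thousands,
financial proxies spanning four orders of magnitude (tens of AUD for a
gastro episode up to ~90k AUD for annual earnings, hence log-uniform
sampling), benefit durations drawn from the published groupings
{2, 3, 15, 30} years, and impact adjustments well inside [0, 0.9].

Investment is drawn as a fraction of the expected total annual benefit so
generated ratios stay in a plausible band and are always defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import total_annual_benefit
from .model import ImpactAdjustments, OutcomeSpec, Scenario, validate_scenario

__all__ = ["GeneratorSpec", "generate_scenario", "generate_suite"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Sampling ranges for random scenarios. All ranges inclusive."""

    n_outcomes: int = 8
    seed: int = 0
    incidence_range: tuple[float, float] = (0.001, 1.0)
    risk_reduction_range: tuple[float, float] = (0.02, 0.6)
    unit_value_range: tuple[float, float] = (20.0, 90_000.0)  # log-uniform
    duration_choices: tuple[int, ...] = (2, 3, 15, 30)
    deadweight_range: tuple[float, float] = (0.0, 0.3)
    displacement_range: tuple[float, float] = (0.0, 0.3)
    attribution_range: tuple[float, float] = (0.0, 0.4)
    drop_off_range: tuple[float, float] = (0.0, 0.5)
    discount_rate_range: tuple[float, float] = (0.0, 0.08)
    population_range: tuple[int, int] = (200, 5_000)
    investment_fraction_range: tuple[float, float] = (0.005, 0.2)

    def validate(self) -> None:
        if self.n_outcomes < 1:
            raise ValueError("n_outcomes must be >= 1")
        if not self.duration_choices or any(d < 1 for d in self.duration_choices):
            raise ValueError("duration_choices must be positive integers")
        bounded = {
            "incidence_range": (self.incidence_range, 0.0, 1.0),
            "risk_reduction_range": (self.risk_reduction_range, 0.0, 1.0),
            "deadweight_range": (self.deadweight_range, 0.0, 0.9),
            "displacement_range": (self.displacement_range, 0.0, 0.9),
            "attribution_range": (self.attribution_range, 0.0, 0.9),
            "drop_off_range": (self.drop_off_range, 0.0, 0.9),
        }
        for name, ((lo, hi), bmin, bmax) in bounded.items():
            if not (bmin <= lo <= hi <= bmax):
                raise ValueError(f"{name} must satisfy {bmin} <= lo <= hi <= {bmax}")
        for name, (lo, hi) in {
            "unit_value_range": self.unit_value_range,
            "investment_fraction_range": self.investment_fraction_range,
        }.items():
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval")
        lo, hi = self.population_range
        if not (1 <= lo <= hi):
            raise ValueError("population_range must satisfy 1 <= lo <= hi")
        if self.discount_rate_range[0] < 0 or (
            self.discount_rate_range[0] > self.discount_rate_range[1]
        ):
            raise ValueError("discount_rate_range must be a non-negative interval")


def _uniform(rng: np.random.Generator, interval: tuple[float, float]) -> float:
    lo, hi = interval
    return lo if lo == hi else float(rng.uniform(lo, hi))


def _log_uniform(rng: np.random.Generator, interval: tuple[float, float]) -> float:
    lo, hi = interval
    return lo if lo == hi else float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_scenario(spec: GeneratorSpec) -> Scenario:
    """Deterministically sample one valid scenario from ``spec``.

    Identical specs (including seed) give identical scenarios.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    outcomes = []
    for i in range(spec.n_outcomes):
        outcomes.append(
            OutcomeSpec(
                name=f"outcome-{i + 1:02d}",
                beneficiary="infant" if rng.random() < 0.5 else "mother",
                incidence=_uniform(rng, spec.incidence_range),
                risk_reduction=_uniform(rng, spec.risk_reduction_range),
                unit_value=_log_uniform(rng, spec.unit_value_range),
                duration_years=int(rng.choice(np.asarray(spec.duration_choices))),
            )
        )
    adjustments = ImpactAdjustments(
        deadweight=_uniform(rng, spec.deadweight_range),
        displacement=_uniform(rng, spec.displacement_range),
        attribution=_uniform(rng, spec.attribution_range),
        drop_off=_uniform(rng, spec.drop_off_range),
    )
    population = int(rng.integers(spec.population_range[0], spec.population_range[1] + 1))
    partial = Scenario(
        name=f"synthetic-{spec.seed}",
        population=population,
        breastfeeding_rate=float(rng.uniform(0.3, 1.0)),
        outcomes=tuple(outcomes),
        investment=1.0,  # placeholder until the benefit total is known
        discount_rate=_uniform(rng, spec.discount_rate_range),
        adjustments=adjustments,
    )
    expected_total = total_annual_benefit(partial)
    fraction = _uniform(rng, spec.investment_fraction_range)
    # guard: even a degenerate all-zero-benefit draw keeps investment > 0
    investment = max(expected_total * fraction, 1e-6)
    scenario = Scenario(
        name=partial.name,
        population=partial.population,
        breastfeeding_rate=partial.breastfeeding_rate,
        outcomes=partial.outcomes,
        investment=investment,
        discount_rate=partial.discount_rate,
        adjustments=partial.adjustments,
    )
    report = validate_scenario(scenario)
    assert report.ok, f"generator produced invalid scenario: {report.violations}"
    return scenario


def generate_suite(spec: GeneratorSpec, count: int) -> list[Scenario]:
    """``count`` scenarios from consecutive seeds spec.seed, spec.seed+1, ..."""
    if count < 1:
        raise ValueError("count must be >= 1")
    from dataclasses import replace

    return [generate_scenario(replace(spec, seed=spec.seed + k)) for k in range(count)]
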