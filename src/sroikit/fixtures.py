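"""Built-in case study: BFHI accreditation at Calvary Public Hospital.

The scenario encodes the published valuation of maintaining Baby-Friendly
Hospital Initiative accreditation in a Canberra public maternity unit with
about 1000 births per year: 14 outcome lines (9 infant, 5 maternal), impact
adjustments of 5% deadweight, 20% displacement, 25% attribution and 20%
annual drop-off, an annual investment of AUD 24,433.80 and a 4% discount
rate.

Each outcome carries the published annual value (``printed_value``). Seven
lines reproduce exactly from the engine's valuation formula; the other
seven do not reconcile with their published inputs and are carried at their
printed values so the discrepancy stays visible rather than hidden. The
published grand total (AUD 1,375,050) also differs from the sum of the
published rows (AUD 1,398,140); it is stored as ``total_benefit_override``
so headline-ratio reproduction can use the published total while row-level
arithmetic remains inspectable.
"""

from __future__ import annotations

from .model import ImpactAdjustments, OutcomeSpec, Scenario

__all__ = [
    "calvary_fixture",
    "CALVARY_PRINTED_TOTAL",
    "CALVARY_INVESTMENT",
    "RECONCILABLE_OUTCOMES",
]

CALVARY_PRINTED_TOTAL = 1_375_050.0
CALVARY_INVESTMENT = 24_433.80

#: Outcome lines whose printed annual value equals the engine's formula
#: population x incidence x risk_reduction x unit_value x retention,
#: rounded to the nearest AUD.
RECONCILABLE_OUTCOMES = (
    "Reduce risk of diarrhea",
    "Reduce risk of respiratory infection",
    "Reduce risk of acute otitis media",
    "Higher IQ",
    "Reduce risk of type 1 diabetes",
    "Reduce risk of Sudden Infant Death Syndrome (SIDS)",
    "Reduce risk of hypertension",
)

# (name, beneficiary, incidence, risk reduction, proxy AUD, duration y, printed AUD/y)
_OUTCOME_ROWS = [
    # Infant outcomes. Durations: acute conditions 3 y; lifelong-risk
    # conditions and cognition 30 y.
    ("Reduce risk of diarrhea", "infant", 1.00, 0.26, 20.27, 3, 3_004),
    ("Reduce risk of respiratory infection", "infant", 0.14, 0.18, 2_864, 3, 41_138),
    ("Reduce risk of acute otitis media", "infant", 0.25, 0.43, 594, 3, 36_397),
    ("Reduce risk of necrotizing enterocolitis", "infant", 0.03, 0.38, 13_863, 3, 100_591),
    ("Higher IQ", "infant", 0.00008, 0.0021, 89_487, 30, 9),
    ("Reduce risk of obesity", "infant", 0.67, 0.26, 2_500, 30, 276_832),
    ("Reduce risk of type 1 diabetes", "infant", 0.00012, 0.55, 3_131, 30, 118),
    ("Reduce risk of type 2 diabetes", "infant", 0.05, 0.35, 3_131, 30, 33_106),
    ("Reduce risk of Sudden Infant Death Syndrome (SIDS)", "infant", 0.03, 0.40, 89_487, 30, 612_091),
    # Maternal outcomes: chronic-disease risk 15 y; formula purchase 2 y.
    ("Reduce risk of breast cancer", "mother", 0.13, 0.04, 36_448, 15, 111_668),
    ("Reduce risk of cardiovascular disease", "mother", 0.05, 0.09, 1_700, 15, 4_186),
    ("Not buying formula", "mother", 0.97, 0.154, 1_160, 2, 121_859),
    ("Reduce risk of ovarian cancer", "mother", 0.01, 0.24, 31_958, 15, 52_462),
    ("Reduce risk of hypertension", "mother", 0.12, 0.12, 570, 15, 4_679),
]


def calvary_fixture() -> Scenario:
    """The Calvary Public Hospital BFHI scenario, published inputs verbatim."""
    outcomes = tuple(
        OutcomeSpec(
            name=name,
            beneficiary=who,
            incidence=inc,
            risk_reduction=rr,
            unit_value=float(unit),
            duration_years=dur,
            printed_value=float(printed),
        )
        for name, who, inc, rr, unit, dur, printed in _OUTCOME_ROWS
    )
    return Scenario(
        name="calvary-bfhi",
        population=1000,
        breastfeeding_rate=0.97,
        outcomes=outcomes,
        investment=CALVARY_INVESTMENT,
        discount_rate=0.04,
        adjustments=ImpactAdjustments(
            deadweight=0.05, displacement=0.20, attribution=0.25, drop_off=0.20
        ),
        total_benefit_override=CALVARY_PRINTED_TOTAL,
    )
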