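"""Domain types, validation and scenario I/O for SROI analyses.

An SROI (Social Return on Investment) scenario describes a yearly cohort of
mother–infant dyads served by a program (here: a BFHI-accredited maternity
unit), a list of preventable-condition outcomes valued through financial
proxies, the impact adjustments of the SROI framework (deadweight,
displacement, attribution, drop-off), the annual program investment and a
discount rate.

Per outcome the valuation inputs are: the condition's prevalence or
incidence in the cohort, the relative risk reduction attributable to
breastfeeding (sourced from odds ratios in the epidemiological literature),
a financial proxy in AUD per case (or per person-year for earnings-based
proxies), and the number of years the benefit stream persists.

Scenarios load from YAML or JSON files, or from a "CSV bundle" — a
directory holding ``scenario.yaml`` for the scalar fields plus
``outcomes.csv`` with header
``name,beneficiary,incidence,risk_reduction,unit_value,duration_years``.
Fractions may be written either as decimals (``0.26``) or percent strings
(``"26%"``).
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = [
    "Beneficiary",
    "OutcomeSpec",
    "ImpactAdjustments",
    "Scenario",
    "ValidationReport",
    "SchemaError",
    "FractionParseError",
    "ScenarioValidationError",
    "parse_fraction",
    "load_scenario",
    "write_scenario",
    "validate_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
]

BENEFICIARIES = ("infant", "mother")
Beneficiary = str  # one of BENEFICIARIES

OUTCOME_CSV_HEADER = [
    "name",
    "beneficiary",
    "incidence",
    "risk_reduction",
    "unit_value",
    "duration_years",
]


class SchemaError(ValueError):
    """A required field is missing or has the wrong structure."""


class FractionParseError(ValueError):
    """A fraction token could not be parsed as a decimal or percent string."""

    def __init__(self, token: object, where: str = ""):
        self.token = token
        loc = f" in {where}" if where else ""
        super().__init__(f"cannot parse fraction from {token!r}{loc}")


class ScenarioValidationError(ValueError):
    """Raised by loaders when a parsed scenario violates an invariant."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = "; ".join(f"{p}: {m}" for p, m in report.violations)
        super().__init__(f"invalid scenario: {lines}")


def parse_fraction(value: object, where: str = "") -> float:
    """Parse a fraction from decimal (``0.26``) or percent (``"26%"``) notation.

    Percent strings divide by 100, so ``"0.008%"`` becomes ``0.00008``
    (percent-of-one convention throughout). Plain numeric strings are
    accepted as decimals.
    """
    if isinstance(value, bool):
        raise FractionParseError(value, where)
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        tok = value.strip()
        try:
            if tok.endswith("%"):
                return float(tok[:-1].strip()) / 100.0
            return float(tok)
        except ValueError:
            raise FractionParseError(value, where) from None
    raise FractionParseError(value, where)


@dataclass(frozen=True)
class OutcomeSpec:
    """One preventable-condition benefit line.

    ``incidence`` is the condition's prevalence/incidence in the reference
    population; ``risk_reduction`` the relative risk reduction attributable
    to breastfeeding; ``unit_value`` the financial proxy in AUD per affected
    case (or per person-year for earnings proxies); ``duration_years`` how
    long the benefit stream persists. ``printed_value`` optionally carries a
    published per-year value for this line so that discrepancies between a
    source table and the engine's own arithmetic stay visible.
    """

    name: str
    beneficiary: Beneficiary
    incidence: float
    risk_reduction: float
    unit_value: float
    duration_years: int
    printed_value: Optional[float] = None


@dataclass(frozen=True)
class ImpactAdjustments:
    """SROI impact-adjustment fractions.

    deadweight: share of the outcome that would have occurred anyway;
    displacement: share that merely displaced other beneficial activity;
    attribution: share caused by other actors/interventions;
    drop_off: annual decay rate of the benefit in later years.
    """

    deadweight: float
    displacement: float
    attribution: float
    drop_off: float

    @property
    def retention(self) -> float:
        """Combined retention factor (1-dw)(1-disp)(1-attr)."""
        return (
            (1.0 - self.deadweight)
            * (1.0 - self.displacement)
            * (1.0 - self.attribution)
        )


@dataclass(frozen=True)
class Scenario:
    """A complete SROI valuation scenario.

    ``population`` counts mother–infant dyads per year. ``breastfeeding_rate``
    is descriptive metadata and is not multiplied into the valuation unless
    ``apply_breastfeeding_rate`` is set. ``total_benefit_override``, when
    present, replaces the computed outcome-sum as the benefit basis in ratio
    calculations (used when reproducing a published total that does not
    exactly equal its published rows).
    """

    population: int
    breastfeeding_rate: float
    outcomes: tuple[OutcomeSpec, ...]
    investment: float
    discount_rate: float
    adjustments: ImpactAdjustments
    total_benefit_override: Optional[float] = None
    apply_breastfeeding_rate: bool = False
    name: str = "scenario"

    def outcome(self, name: str) -> OutcomeSpec:
        """Look up an outcome by its label."""
        for o in self.outcomes:
            if o.name == name:
                return o
        raise KeyError(f"no outcome named {name!r}")


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[tuple[str, str], ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations


def _check(violations: list, cond: bool, path: str, msg: str) -> None:
    if not cond:
        violations.append((path, msg))


def validate_scenario(s: Scenario) -> ValidationReport:
    """Check every domain invariant; violations are returned as data.

    Never raises on invalid content and never mutates the input.
    """
    v: list[tuple[str, str]] = []
    _check(v, s.population >= 1, "population", "must be >= 1")
    _check(v, s.investment > 0, "investment", "must be > 0")
    _check(v, len(s.outcomes) >= 1, "outcomes", "at least one outcome required")
    _check(v, 0.0 <= s.breastfeeding_rate <= 1.0, "breastfeeding_rate", "must be in [0, 1]")
    _check(v, s.discount_rate >= 0.0, "discount_rate", "must be >= 0")
    if s.total_benefit_override is not None:
        _check(v, s.total_benefit_override >= 0, "total_benefit_override", "must be >= 0")

    a = s.adjustments
    for fname in ("deadweight", "displacement", "attribution", "drop_off"):
        val = getattr(a, fname)
        _check(v, 0.0 <= val < 1.0, f"adjustments.{fname}", "must be in [0, 1)")
    _check(
        v,
        0.0 < a.retention <= 1.0,
        "adjustments",
        "combined retention factor (1-dw)(1-disp)(1-attr) must lie in (0, 1]",
    )

    seen: set[str] = set()
    for i, o in enumerate(s.outcomes):
        path = f"outcomes[{o.name or i}]"
        _check(v, bool(o.name), f"{path}.name", "must be non-empty")
        _check(v, o.name not in seen, f"{path}.name", "duplicate outcome name")
        seen.add(o.name)
        _check(v, o.beneficiary in BENEFICIARIES, f"{path}.beneficiary",
               f"must be one of {BENEFICIARIES}")
        _check(v, 0.0 <= o.incidence <= 1.0, f"{path}.incidence", "must be in [0, 1]")
        _check(v, 0.0 <= o.risk_reduction <= 1.0, f"{path}.risk_reduction",
               "must be in [0, 1]")
        _check(v, o.unit_value >= 0.0, f"{path}.unit_value", "must be >= 0")
        _check(v, isinstance(o.duration_years, int) and o.duration_years >= 1,
               f"{path}.duration_years", "must be an integer >= 1")
    return ValidationReport(tuple(v))


# ---------------------------------------------------------------------------
# dict <-> dataclass conversion


def _require(d: dict, key: str, where: str) -> object:
    if key not in d:
        raise SchemaError(f"missing required field {key!r} in {where}")
    return d[key]


def _outcome_from_dict(d: dict, where: str = "outcome") -> OutcomeSpec:
    name = str(_require(d, "name", where))
    where = f"outcome {name!r}"
    dur_raw = _require(d, "duration_years", where)
    try:
        duration = int(dur_raw)
    except (TypeError, ValueError):
        raise SchemaError(f"duration_years must be an integer in {where}, got {dur_raw!r}")
    printed = d.get("printed_value")
    return OutcomeSpec(
        name=name,
        beneficiary=str(_require(d, "beneficiary", where)),
        incidence=parse_fraction(_require(d, "incidence", where), f"{where}.incidence"),
        risk_reduction=parse_fraction(
            _require(d, "risk_reduction", where), f"{where}.risk_reduction"
        ),
        unit_value=float(_require(d, "unit_value", where)),
        duration_years=duration,
        printed_value=None if printed is None else float(printed),
    )


def scenario_from_dict(d: dict) -> Scenario:
    """Build a Scenario from a parsed mapping; raises SchemaError on gaps."""
    if not isinstance(d, dict):
        raise SchemaError("scenario document must be a mapping")
    adj_d = _require(d, "adjustments", "scenario")
    if not isinstance(adj_d, dict):
        raise SchemaError("adjustments must be a mapping")
    adj = ImpactAdjustments(
        deadweight=parse_fraction(_require(adj_d, "deadweight", "adjustments"),
                                  "adjustments.deadweight"),
        displacement=parse_fraction(_require(adj_d, "displacement", "adjustments"),
                                    "adjustments.displacement"),
        attribution=parse_fraction(_require(adj_d, "attribution", "adjustments"),
                                   "adjustments.attribution"),
        drop_off=parse_fraction(_require(adj_d, "drop_off", "adjustments"),
                                "adjustments.drop_off"),
    )
    outcomes_raw = _require(d, "outcomes", "scenario")
    if not isinstance(outcomes_raw, list):
        raise SchemaError("outcomes must be a list")
    outcomes = tuple(_outcome_from_dict(o) for o in outcomes_raw)
    override = d.get("total_benefit_override")
    return Scenario(
        population=int(_require(d, "population", "scenario")),
        breastfeeding_rate=parse_fraction(
            _require(d, "breastfeeding_rate", "scenario"), "breastfeeding_rate"
        ),
        outcomes=outcomes,
        investment=float(_require(d, "investment", "scenario")),
        discount_rate=parse_fraction(
            _require(d, "discount_rate", "scenario"), "discount_rate"
        ),
        adjustments=adj,
        total_benefit_override=None if override is None else float(override),
        apply_breastfeeding_rate=bool(d.get("apply_breastfeeding_rate", False)),
        name=str(d.get("name", "scenario")),
    )


def scenario_to_dict(s: Scenario) -> dict:
    """Plain-dict form of a Scenario (decimal fractions, JSON/YAML-safe)."""
    d = {
        "name": s.name,
        "population": s.population,
        "breastfeeding_rate": s.breastfeeding_rate,
        "investment": s.investment,
        "discount_rate": s.discount_rate,
        "apply_breastfeeding_rate": s.apply_breastfeeding_rate,
        "adjustments": dataclasses.asdict(s.adjustments),
        "outcomes": [
            {k: v for k, v in dataclasses.asdict(o).items()
             if not (k == "printed_value" and v is None)}
            for o in s.outcomes
        ],
    }
    if s.total_benefit_override is not None:
        d["total_benefit_override"] = s.total_benefit_override
    return d


# ---------------------------------------------------------------------------
# file I/O


def _load_outcomes_csv(path: Path) -> list[dict]:
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"empty outcomes CSV {path}")
        missing = [c for c in OUTCOME_CSV_HEADER if c not in reader.fieldnames]
        if missing:
            raise SchemaError(
                f"outcomes CSV missing required column(s) {missing} in {path}"
            )
        rows = []
        for row in reader:
            row = dict(row)
            if row.get("printed_value") in ("", None):
                row.pop("printed_value", None)
            rows.append(row)
        return rows


def load_scenario(path: Union[str, Path], format: Optional[str] = None) -> Scenario:
    """Load and validate a scenario from YAML, JSON or a CSV bundle.

    ``format`` is one of ``yaml``, ``json``, ``csv_bundle``; when omitted it
    is inferred from the path (directory -> csv_bundle, else suffix).
    Raises SchemaError / FractionParseError on structural problems and
    ScenarioValidationError when invariants are violated.
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "csv_bundle"
        elif path.suffix in (".yaml", ".yml"):
            format = "yaml"
        elif path.suffix == ".json":
            format = "json"
        else:
            raise SchemaError(f"cannot infer scenario format from {path}")

    if format == "csv_bundle":
        scalar_path = None
        for candidate in ("scenario.yaml", "scenario.yml", "scenario.json"):
            if (path / candidate).exists():
                scalar_path = path / candidate
                break
        if scalar_path is None:
            raise FileNotFoundError(f"no scenario.yaml/json inside bundle {path}")
        if scalar_path.suffix == ".json":
            doc = json.loads(scalar_path.read_text())
        else:
            doc = yaml.safe_load(scalar_path.read_text())
        doc = doc or {}
        doc["outcomes"] = _load_outcomes_csv(path / "outcomes.csv")
    elif format == "yaml":
        doc = yaml.safe_load(path.read_text())
    elif format == "json":
        doc = json.loads(path.read_text())
    else:
        raise SchemaError(f"unknown scenario format {format!r}")

    s = scenario_from_dict(doc)
    report = validate_scenario(s)
    if not report.ok:
        raise ScenarioValidationError(report)
    return s


def write_scenario(s: Scenario, path: Union[str, Path], format: str = "yaml") -> Path:
    """Write a scenario in a form load_scenario reads back identically."""
    path = Path(path)
    d = scenario_to_dict(s)
    if format == "yaml":
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    elif format == "json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    elif format == "csv_bundle":
        path.mkdir(parents=True, exist_ok=True)
        outcomes = d.pop("outcomes")
        (path / "scenario.yaml").write_text(yaml.safe_dump(d, sort_keys=True))
        with (path / "outcomes.csv").open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=OUTCOME_CSV_HEADER + ["printed_value"])
            writer.writeheader()
            for o in outcomes:
                writer.writerow(o)
    else:
        raise SchemaError(f"unknown scenario format {format!r}")
    return path
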