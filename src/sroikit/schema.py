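"""Published JSON-schema document for scenario configuration files.

The same schema covers the YAML and JSON dialects (YAML documents are
mapped to JSON-equivalent structures before validation). Fraction-valued
fields accept either a number in [0, 1] or a percent string like "26%"
(divided by 100 on load, so "0.008%" means 0.00008).
"""

from __future__ import annotations

import json

__all__ = ["SCENARIO_SCHEMA", "scenario_json_schema"]

_FRACTION = {
    "oneOf": [
        {"type": "number", "minimum": 0, "maximum": 1},
        {"type": "string", "pattern": r"^\s*[0-9.eE+-]+\s*%?\s*$"},
    ]
}

SCENARIO_SCHEMA: dict = {
    "$schema": "https://json-schema.org/draft/2020-12/schema",
    "title": "SROI scenario",
    "type": "object",
    "required": [
        "population",
        "breastfeeding_rate",
        "outcomes",
        "investment",
        "discount_rate",
        "adjustments",
    ],
    "properties": {
        "name": {"type": "string"},
        "population": {"type": "integer", "minimum": 1},
        "breastfeeding_rate": _FRACTION,
        "investment": {"type": "number", "exclusiveMinimum": 0},
        "discount_rate": _FRACTION,
        "apply_breastfeeding_rate": {"type": "boolean"},
        "total_benefit_override": {"type": "number", "minimum": 0},
        "adjustments": {
            "type": "object",
            "required": ["deadweight", "displacement", "attribution", "drop_off"],
            "properties": {
                "deadweight": _FRACTION,
                "displacement": _FRACTION,
                "attribution": _FRACTION,
                "drop_off": _FRACTION,
            },
        },
        "outcomes": {
            "type": "array",
            "minItems": 1,
            "items": {
                "type": "object",
                "required": [
                    "name",
                    "beneficiary",
                    "incidence",
                    "risk_reduction",
                    "unit_value",
                    "duration_years",
                ],
                "properties": {
                    "name": {"type": "string", "minLength": 1},
                    "beneficiary": {"enum": ["infant", "mother"]},
                    "incidence": _FRACTION,
                    "risk_reduction": _FRACTION,
                    "unit_value": {"type": "number", "minimum": 0},
                    "duration_years": {"type": "integer", "minimum": 1},
                    "printed_value": {"type": "number", "minimum": 0},
                },
            },
        },
    },
}


def scenario_json_schema(indent: int = 2) -> str:
    """The scenario schema as a JSON document string."""
    return json.dumps(SCENARIO_SCHEMA, indent=indent)
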