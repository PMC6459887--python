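"""Pydantic schema for the pipeline's JSON report.

``validate_report`` raises ``pydantic.ValidationError`` on a malformed
report dictionary; the CLI validates every report before writing it.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PooledBlock(_Strict):
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    def __init__(self, **data):  # accept the JSON key "or"
        if "or" in data:
            data["or_"] = data.pop("or")
        super().__init__(**data)


class HeterogeneityBlock(_Strict):
    Q: float
    df: int
    p_value: float
    i_squared_pct: float


class VariantRow(_Strict):
    variant_id: str
    ratio: float
    se: float
    ci_low: float
    ci_high: float
    weight: float


class LooRow(_Strict):
    omitted_variant: str
    or_: float
    ci_low: float
    ci_high: float
    fluctuation: float

    def __init__(self, **data):
        if "or" in data:
            data["or_"] = data.pop("or")
        super().__init__(**data)


class EggerBlock(_Strict):
    slope: float
    slope_se: float
    slope_ci_low: float
    slope_ci_high: float
    slope_p: float
    intercept: float
    intercept_se: float
    intercept_ci_low: float
    intercept_ci_high: float
    intercept_p: float
    n_instruments: int
    overdispersion: float


class MrReport(_Strict):
    generated_at: str
    package_version: str
    provenance: str
    se_method: str
    n_instruments: int
    pooled: PooledBlock
    heterogeneity: HeterogeneityBlock | None
    variants: list[VariantRow]
    leave_one_out: list[LooRow] | None
    egger: EggerBlock | None


def validate_report(report: dict) -> MrReport:
    """Validate a report dict against the schema; returns the parsed model."""
    return MrReport(**report)
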