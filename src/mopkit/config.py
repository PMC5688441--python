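"""Analysis configuration shared by the orchestration and family-planning
modules."""

from __future__ import annotations

from enum import Enum
from pathlib import Path

import pydantic
import yaml

__all__ = ["AnalysisConfig", "GroupBy", "load_config"]


class GroupBy(str, Enum):
    NONE = "none"
    OUTCOME = "outcome"
    DELIVERY_POINT = "delivery_point"
    CAUSE = "cause"


class AnalysisConfig(pydantic.BaseModel):
    """Knobs of a missed-opportunity run.

    ``target_coverage`` (default 0.90) is the aspirational coverage every
    intervention is scaled up to, one at a time; interventions already at or
    above it are left as-is.  ``unmet_need_floor`` (default 0.10) is the level
    unmet need for contraception is reduced to in the family-planning
    scenario.  ``top_n`` (default 20) truncates ranked displays.
    ``u5mr_threshold`` (default 20 deaths per 1,000 live births) is the
    country-inclusion cut-off for multi-country runs.
    """

    model_config = pydantic.ConfigDict(frozen=True)

    target_coverage: float = 0.90
    unmet_need_floor: float = 0.10
    include_family_planning: bool = True
    top_n: int = 20
    group_by: GroupBy = GroupBy.NONE
    include_stillbirths_in_total: bool = True
    u5mr_threshold: float = 20.0

    @pydantic.field_validator("target_coverage")
    @classmethod
    def _target_in_unit_interval(cls, v: float) -> float:
        if not (0.0 < v <= 1.0):
            raise ValueError("target_coverage must be in (0, 1]")
        return v

    @pydantic.field_validator("unmet_need_floor")
    @classmethod
    def _floor_in_unit_interval(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError("unmet_need_floor must be in [0, 1]")
        return v

    @pydantic.field_validator("top_n")
    @classmethod
    def _top_n_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("top_n must be >= 1")
        return v


def load_config(path: str | Path, **overrides) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file; keyword arguments
    (e.g. CLI flags) override file values."""
    payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    payload.update({k: v for k, v in overrides.items() if v is not None})
    return AnalysisConfig.model_validate(payload)
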