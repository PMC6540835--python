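"""YAML survey configuration.

A config file carries the survey frame and model choices that are not part
of the observation/transect tables::

    w: 600.0            # strip half-width, m
    sides: 1            # sides of the line searched
    area_km2: 8000.0    # study area
    form: two_piece_normal
    covariates: [cover]
    left_truncation: 0.0   # or "auto"
    seed: 1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

__all__ = ["SurveyConfig", "load_config"]

_FORMS = ("half_normal", "two_piece_normal")


@dataclass
class SurveyConfig:
    w: float
    area_km2: float
    sides: int = 1
    form: str = "two_piece_normal"
    covariates: tuple[str, ...] = ()
    mr_covariates: tuple[str, ...] = ()
    left_truncation: float | str = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValidationError(f"config: w must be positive, got {self.w}")
        if self.area_km2 <= 0:
            raise ValidationError("config: area_km2 must be positive")
        if self.sides not in (1, 2):
            raise ValidationError(f"config: sides must be 1 or 2, got {self.sides}")
        if self.form not in _FORMS:
            raise ValidationError(f"config: unknown form {self.form!r}")
        if isinstance(self.left_truncation, str) and self.left_truncation != "auto":
            raise ValidationError("config: left_truncation must be a number or 'auto'")
        self.covariates = tuple(self.covariates or ())
        self.mr_covariates = tuple(self.mr_covariates or ())


def load_config(path: str | Path) -> SurveyConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} is not a mapping")
    known = {f for f in SurveyConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"config: unknown key(s): {', '.join(sorted(unknown))}")
    missing = {"w", "area_km2"} - set(raw)
    if missing:
        raise ValidationError(f"config: missing key(s): {', '.join(sorted(missing))}")
    return SurveyConfig(**raw)
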