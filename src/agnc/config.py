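"""Tool configuration: vocabulary overrides and scanner/counter settings."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .ecc import DEFAULT_CLADE_LADDER, DEFAULT_EXPRESSION_CODES
from .errors import ConfigError


@dataclass
class ToolConfig:
    clade_ladder: tuple[str, ...] = DEFAULT_CLADE_LADDER
    expression_codes: tuple[str, ...] = DEFAULT_EXPRESSION_CODES
    synteny_max_gap: int = 0
    str_min_unit: int = 1
    str_max_unit: int = 6
    str_min_copies: int = 2
    registry_path: str | None = None
    output_format: str = "tsv"
    seed: int = 0

    def __post_init__(self) -> None:
        self.clade_ladder = tuple(self.clade_ladder)
        self.expression_codes = tuple(self.expression_codes)
        if len(set(self.clade_ladder)) != len(self.clade_ladder):
            raise ConfigError("clade_ladder tokens must be unique")
        if len(set(self.expression_codes)) != len(self.expression_codes):
            raise ConfigError("expression_codes must be unique")
        if self.synteny_max_gap < 0:
            raise ConfigError("synteny_max_gap must be non-negative")
        if not (1 <= self.str_min_unit <= self.str_max_unit):
            raise ConfigError("need 1 <= str_min_unit <= str_max_unit")
        if self.str_min_copies < 2:
            raise ConfigError("str_min_copies must be at least 2")
        if self.output_format not in ("tsv", "json"):
            raise ConfigError("output_format must be 'tsv' or 'json'")


def load_config(path) -> ToolConfig:
    """Load a YAML config; unknown keys are rejected, not ignored."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(ToolConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return ToolConfig(**raw)
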