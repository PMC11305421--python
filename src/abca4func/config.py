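"""Run configuration: one YAML file validated up front.

Unknown keys are rejected so a typo in a threshold name can never silently
fall back to a default, and every output table records the configuration it
was produced with in its header lines.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError
from .evidence import RuleConfig
from .findex import SeverityBands


@dataclass(frozen=True)
class RunConfig:
    rules: RuleConfig = field(default_factory=RuleConfig)
    bands: SeverityBands = field(default_factory=SeverityBands)
    wt_id: str = "WT"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"configuration must be a mapping, got {type(raw).__name__}")
        known = {"rules", "bands", "wt_id", "seed", "log_level"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        try:
            rules = RuleConfig(**_section(raw, "rules", RuleConfig))
            bands = SeverityBands(**_section(raw, "bands", SeverityBands))
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        return cls(
            rules=rules,
            bands=bands,
            wt_id=raw.get("wt_id", "WT"),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )

    def header_lines(self) -> list[str]:
        lines = [f"abca4func {__version__}"]
        for section, obj in (("rules", self.rules), ("bands", self.bands)):
            for key, value in asdict(obj).items():
                lines.append(f"{section}.{key} = {value}")
        lines.append(f"wt_id = {self.wt_id}")
        lines.append(f"seed = {self.seed}")
        return lines


def _section(raw: dict, name: str, cls) -> dict:
    section = raw.get(name, {})
    if not isinstance(section, dict):
        raise ConfigError(f"configuration section {name!r} must be a mapping")
    known = {f for f in cls.__dataclass_fields__}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    return section
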