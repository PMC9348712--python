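"""Run configuration: YAML schema, validation, manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .scenarios import Scenario, get_scenario


class ConfigError(ValueError):
    """Schema violation; carries one message per offending field."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  " + "\n  ".join(problems))


@dataclass
class RunConfig:
    """Top-level run description.

    Either names a built-in scenario or inlines a full scenario dict; the
    remaining knobs (seed, γ, dosing, coarse mode, durations) override the
    scenario defaults.
    """

    scenario: str | None = None
    scenario_inline: dict | None = None
    output_dir: str = "out"
    snapshot_interval: float = 5.0   # days
    seed: int = 0
    duration: float | None = None
    gamma: float | None = None
    dosing: bool = False
    coarse: bool = False
    overrides: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        problems = []
        if self.scenario is None and self.scenario_inline is None:
            problems.append("scenario: either a scenario name or an inline "
                            "scenario block is required")
        if self.snapshot_interval <= 0:
            problems.append("snapshot_interval: must be positive")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            problems.append("seed: must be a non-negative integer")
        if self.gamma is not None and self.gamma < 1:
            problems.append("gamma: must be >= 1")
        if self.duration is not None and self.duration <= 0:
            problems.append("duration: must be positive")
        if problems:
            raise ConfigError(problems)

    def resolve_scenario(self) -> Scenario:
        self.validate()
        if self.scenario_inline is not None:
            sc = Scenario.from_dict(self.scenario_inline)
        else:
            try:
                sc = get_scenario(self.scenario, dosing=self.dosing)
            except KeyError as exc:
                raise ConfigError([f"scenario: {exc.args[0]}"]) from exc
        if self.duration is not None:
            sc.duration = self.duration
        if self.gamma is not None:
            sc.coupling.gamma = float(self.gamma)
        if self.coarse:
            sc.coupling.mode = "coarse"
        if self.dosing:
            sc.dose.enabled = True
        sc.seed = self.seed
        for key, val in self.overrides.items():
            section, _, name = key.partition(".")
            target = {"rule_params": sc.rule_params, "qsp_params": sc.qsp_params,
                      "coupling": sc.coupling, "dose": sc.dose}.get(section)
            if target is None or not hasattr(target, name):
                raise ConfigError([f"overrides: unknown parameter {key!r}"])
            setattr(target, name, val)
        return sc


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(["top level: expected a mapping"])
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError([f"{k}: unknown field" for k in sorted(unknown)])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def dump_scenario(sc: Scenario) -> str:
    """Scenario to YAML; parses back to an identical scenario."""
    return yaml.safe_dump(sc.to_dict(), sort_keys=True)


def load_scenario(text: str) -> Scenario:
    return Scenario.from_dict(yaml.safe_load(text))


def write_manifest(out_dir: Path, cfg: RunConfig, extra: dict | None = None) -> Path:
    """Record what produced the outputs: config hash, seed, version."""
    from . import __version__
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest = {
        "config": asdict(cfg),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": cfg.seed,
        "version": __version__,
    }
    manifest.update(extra or {})
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
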