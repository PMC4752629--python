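"""Run configuration: YAML loading, validation and defaults.

A run config ties every stage together under one mandatory master seed.
Unknown keys are an error in strict mode (the default), a warning with
``lax=True``; schema violations are reported with their field path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import SynthConfig
from .econ import CostConfig, EffectConfig
from .pathway import PathwayThresholds

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    """A configuration problem, naming the offending field."""


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``synth``, ``thresholds``, ``costs`` and ``effects`` hold keyword
    overrides for :class:`SynthConfig`, :class:`PathwayThresholds`,
    :class:`CostConfig` and :class:`EffectConfig`; anything not overridden
    keeps the package default.
    """

    master_seed: int
    n_individuals: int = 20000
    cap: int | None = None
    compliance_prob: float = 0.983
    response_probs: tuple[float, float] = (0.307, 0.092)
    risk_threshold: float = 0.05
    second_questionnaire_prob: float = 0.684
    consent_prob: float = 0.681
    mean_rr: float = 5.0
    synth: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    costs: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    n_bootstrap: int = 1000
    output_dir: str | None = None
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.master_seed is None:
            raise ConfigError("missing required field: master_seed")
        if not 0.0 <= self.compliance_prob <= 1.0:
            raise ConfigError("compliance_prob outside [0, 1]")
        # fail early on bad nested overrides, naming the section
        self.synth_config()
        self.pathway_thresholds()
        self.cost_config()
        self.effect_config()

    def _build(self, cls, overrides: dict, section: str, **extra):
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigError(f"{section}: unknown keys {sorted(unknown)}")
        try:
            return cls(**{**extra, **overrides})
        except (TypeError, ValueError) as e:
            raise ConfigError(f"{section}: {e}") from e

    def synth_config(self, n: int | None = None, seed: int | None = None) -> SynthConfig:
        return self._build(
            SynthConfig, self.synth, "synth",
            n_individuals=self.n_individuals if n is None else n,
            seed=self.master_seed if seed is None else seed,
        )

    def pathway_thresholds(self) -> PathwayThresholds:
        return self._build(PathwayThresholds, self.thresholds, "thresholds")

    def cost_config(self) -> CostConfig:
        overrides = self.costs or {
            "screening_workup_cost_pp": 212.0,
            "net_treatment_cost_pp": 60.0,
        }
        return self._build(CostConfig, overrides, "costs")

    def effect_config(self) -> EffectConfig:
        return self._build(EffectConfig, self.effects, "effects")

    def sha256(self) -> str:
        """Stable hash of the configuration (for output provenance blocks)."""
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path, lax: bool = False) -> RunConfig:
    """Load and validate a YAML run config.

    Unknown top-level keys are an error (or a warning with ``lax``);
    defaults are applied for everything absent.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        if lax:
            warnings.warn(f"ignoring unknown config keys: {unknown}", stacklevel=2)
            raw = {k: v for k, v in raw.items() if k in known}
        else:
            raise ConfigError(f"unknown config keys: {unknown}")
    if "master_seed" not in raw:
        raise ConfigError("missing required field: master_seed")
    if "response_probs" in raw:
        raw["response_probs"] = tuple(raw["response_probs"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["response_probs"] = list(config.response_probs)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")
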