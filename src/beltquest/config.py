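"""YAML configuration for simulations and analyses.

A config file has up to four top-level sections, each optional; omitted keys
fall back to the dataclass defaults::

    quest:
      guess: 0.1
      sd: 0.4
      beta: 3.5
      delta: 0.01
      gamma: 0.5
      grid_min: 0.005
      grid_max: 0.9
      grid_step: 0.001
      estimator: mode
    population:
      n: 48
      median_threshold: 0.06
      sigma_log: 0.59
      rho_types: 0.8
      rho_latency: -0.3
    protocol:
      trials_per_block: [25, 35]
      baseline_speed: 1.0
    analysis:
      jzs_prior_scale: 0.707
      beta_prior_width: 0.333
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

from .exceptions import ParameterError
from .observers import PopulationSpec
from .quest import QuestParams
from .session import ProtocolConfig

__all__ = ["RunConfig", "load_config", "quest_params_from_dict",
           "population_from_dict", "protocol_from_dict"]

# config-file spellings that differ from dataclass field names
_QUEST_ALIASES = {"sd": "prior_sd"}


@dataclass(frozen=True)
class RunConfig:
    quest: QuestParams
    population: PopulationSpec
    protocol: ProtocolConfig
    jzs_prior_scale: float = 0.707
    beta_prior_width: float = 0.333


def _build(cls, section: dict, aliases: dict | None = None, listy: tuple = ()):
    known = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in (section or {}).items():
        name = (aliases or {}).get(key, key)
        if name not in known:
            raise ParameterError(f"unknown {cls.__name__} config key: {key!r}")
        if name in listy and isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def quest_params_from_dict(section: dict) -> QuestParams:
    return _build(QuestParams, section, _QUEST_ALIASES)


def population_from_dict(section: dict) -> PopulationSpec:
    return _build(PopulationSpec, section)


def protocol_from_dict(section: dict) -> ProtocolConfig:
    return _build(
        ProtocolConfig, section,
        listy=("baseline_gap_steps", "trials_per_block", "blocks", "clamp"),
    )


def load_config(path=None) -> RunConfig:
    """Load a YAML config file; ``None`` gives the all-defaults config."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    analysis = raw.get("analysis") or {}
    return RunConfig(
        quest=quest_params_from_dict(raw.get("quest")),
        population=population_from_dict(raw.get("population")),
        protocol=protocol_from_dict(raw.get("protocol")),
        jzs_prior_scale=float(analysis.get("jzs_prior_scale", 0.707)),
        beta_prior_width=float(analysis.get("beta_prior_width", 0.333)),
    )
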