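"""YAML configuration for simulated experiments.

A config file holds optional blocks ``body:``, ``protocol:``, ``policy:``,
``gains:`` and ``reward:`` whose keys map onto the corresponding dataclass
fields; omitted keys keep their defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .body import BodyParams
from .ecological import RewardSpec
from .feedback import FeedbackGains
from .plan import PolicyDistribution
from .protocol import ProtocolConfig

__all__ = ["ExperimentConfig", "load_config"]


@dataclasses.dataclass
class ExperimentConfig:
    body: BodyParams
    protocol: ProtocolConfig
    policy: PolicyDistribution
    gains: FeedbackGains
    reward: RewardSpec


def _build(cls, block: dict | None, **extra):
    block = dict(block or {})
    block.update(extra)
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**block)


def load_config(path: str | Path | None = None, seed: int | None = None) -> ExperimentConfig:
    """Load an experiment configuration; ``seed`` overrides the file's."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    protocol_kwargs = {}
    if seed is not None:
        protocol_kwargs["rng_seed"] = int(seed)
    policy_block = dict(data.get("policy") or {})
    for key in ("mean", "stdev"):
        if key in policy_block:
            policy_block[key] = np.asarray(policy_block[key], dtype=float)
    for key in ("kp", "kd"):
        gains_block = data.get("gains") or {}
        if key in gains_block:
            gains_block[key] = tuple(gains_block[key])
    return ExperimentConfig(
        body=_build(BodyParams, data.get("body")),
        protocol=_build(ProtocolConfig, data.get("protocol"), **protocol_kwargs),
        policy=_build(PolicyDistribution, policy_block),
        gains=_build(FeedbackGains, data.get("gains")),
        reward=_build(RewardSpec, data.get("reward")),
    )
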