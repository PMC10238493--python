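"""YAML/JSON configuration round-trip for plant, task, reward and PPO.

Configuration files are flat mappings per section mirroring the dataclass
field names.  SI units throughout, except joint-angle ranges and neutral
angles, which are written in degrees (matching the tabulated convention)
and converted to radians at load time.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import yaml

from .plant import PlantParams
from .task import TaskSpec, RewardWeights
from .ppo import PolicyConfig

__all__ = ["load_config", "save_config", "plant_to_mapping", "plant_from_mapping"]

_DEGREE_FIELDS = ("ankle_angle_range", "hip_angle_range", "neutral_angles")


def plant_to_mapping(params: PlantParams) -> dict:
    d = asdict(params)
    for k in _DEGREE_FIELDS:
        v = d[k]
        d[k] = [math.degrees(x) for x in v] if isinstance(v, (tuple, list)) else math.degrees(v)
    return d


def plant_from_mapping(d: dict) -> PlantParams:
    d = dict(d)
    for k in _DEGREE_FIELDS:
        if k in d:
            v = d[k]
            d[k] = tuple(math.radians(x) for x in v) if isinstance(v, (tuple, list)) \
                else math.radians(v)
    return PlantParams(**d)


def save_config(path, plant: Optional[PlantParams] = None,
                task: Optional[TaskSpec] = None,
                reward: Optional[RewardWeights] = None,
                ppo: Optional[PolicyConfig] = None) -> None:
    doc = {}
    if plant is not None:
        doc["plant"] = plant_to_mapping(plant)
    if task is not None:
        doc["task"] = asdict(task)
    if reward is not None:
        doc["reward"] = asdict(reward)
    if ppo is not None:
        d = asdict(ppo)
        d["hidden_layers"] = list(d["hidden_layers"])
        doc["ppo"] = d
    path = Path(path)
    text = (json.dumps(doc, indent=2) if path.suffix == ".json"
            else yaml.safe_dump(doc, sort_keys=False))
    path.write_text(text)


def load_config(path) -> dict:
    """Load a config file; returns a dict with any of the four sections
    instantiated (keys: plant, task, reward, ppo)."""
    path = Path(path)
    doc = (json.loads(path.read_text()) if path.suffix == ".json"
           else yaml.safe_load(path.read_text()))
    out = {}
    if "plant" in doc:
        out["plant"] = plant_from_mapping(doc["plant"])
    if "task" in doc:
        out["task"] = TaskSpec(**doc["task"])
    if "reward" in doc:
        out["reward"] = RewardWeights(**doc["reward"])
    if "ppo" in doc:
        d = dict(doc["ppo"])
        d["hidden_layers"] = tuple(d["hidden_layers"])
        out["ppo"] = PolicyConfig(**d)
    return out
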