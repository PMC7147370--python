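"""YAML configuration for activations, training and ensembles.

Example::

    activation:
      name: MeLU
      max_input: 255
    training:
      batch_size: 16
      learning_rate: 0.001
      max_epochs: 10
    ensemble:
      n: 10
      max_input: 1
"""

from __future__ import annotations

from dataclasses import fields as _dc_fields
from typing import Optional

import yaml

from .activations import ActivationSpec
from .train_eval import TrainConfig

__all__ = ["load_config", "spec_from_config", "train_config_from_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def spec_from_config(cfg: dict, name: Optional[str] = None,
                     max_input: Optional[float] = None) -> ActivationSpec:
    """Build an ActivationSpec from the ``activation:`` section.

    Explicit ``name`` / ``max_input`` arguments override the file.
    """
    sect = dict(cfg.get("activation", {}))
    if name is not None:
        sect["name"] = name
    if max_input is not None:
        sect["max_input"] = max_input
    if "name" not in sect:
        raise ValueError("no activation name given")
    nm = sect.pop("name")
    mi = sect.pop("max_input", 1.0)
    return ActivationSpec.create(nm, max_input=mi, **sect)


def train_config_from_config(cfg: dict, task: str = "classify") -> TrainConfig:
    """Build a TrainConfig from the ``training:`` section (task defaults)."""
    base = TrainConfig.segmentation() if task == "segment" else TrainConfig.classification()
    sect = dict(cfg.get("training", {}))
    valid = {f.name for f in _dc_fields(TrainConfig)}
    unknown = set(sect) - valid
    if unknown:
        raise ValueError(f"unknown training keys: {sorted(unknown)}")
    from dataclasses import replace
    if "input_size" in sect:
        sect["input_size"] = tuple(sect["input_size"])
    return replace(base, **sect)
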