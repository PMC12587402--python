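"""Declarative YAML configuration for campaigns.

All keys are optional; omitted ones fall back to the package defaults.
Example::

    design_space:
      sorbitol_range: [0, 550]
      arginine_range: [0, 250]
      pH_range: [4.5, 7.5]
      osmolality_range: [100, 600]
    n_init: 13
    batch_size: 5
    n_iterations: 4
    p_exploit: 0.75
    pop: 100
    gens: 100
    seed: 0
    lab:
      sd_tm: 0.2
      sd_kd: 1.5
      sd_rm: 2.0
"""

from __future__ import annotations

from dataclasses import fields

import yaml

from .campaign import CampaignConfig
from .chemistry import DesignSpace
from .virtual_lab import LabConfig

__all__ = ["load_config", "load_lab_config"]


def _pick(data: dict, cls) -> dict:
    names = {f.name for f in fields(cls)}
    out = {}
    for key, value in data.items():
        if key not in names:
            raise KeyError(f"unknown {cls.__name__} key: {key}")
        out[key] = tuple(value) if isinstance(value, list) else value
    return out


def load_config(path) -> tuple[CampaignConfig, LabConfig]:
    """Load (CampaignConfig, LabConfig) from a YAML file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    space = DesignSpace(**_pick(data.pop("design_space", {}), DesignSpace))
    lab = LabConfig(**_pick(data.pop("lab", {}), LabConfig))
    campaign = CampaignConfig(space=space, **_pick(data, CampaignConfig))
    return campaign, lab


def load_lab_config(path) -> LabConfig:
    return load_config(path)[1]
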