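"""YAML configuration loading for the experiment pipelines.

Config files are plain mappings mirroring the experiment config
dataclasses, with two conveniences: tissue properties may be given as a
preset name plus field overrides, and beams as a flat mapping.  Example::

    seed: 7
    phantom:
      tumor:
        diameter_mm: 5.0
        depth_mm: 3.2
        props: {preset: tumor_mimic, mu_a: 250.0}
    beam: {profile: gaussian, diameter_mm: 3.0, pulse_energy_mj: 1.0}
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .phantom import TissueProperties, preset
from .optics import BeamSpec
from .acoustics import GrueneisenModel
from .fusion import KalmanConfig
from .experiments import (DepthAttenuationConfig, HeatSourceReconConfig,
                          PTTwinConfig)

__all__ = [
    "load_yaml",
    "tissue_from_config",
    "beam_from_config",
    "depth_attenuation_config",
    "heat_source_recon_config",
    "ptt_twin_config",
]


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def tissue_from_config(node) -> TissueProperties:
    """Tissue properties from ``{preset: name, <field overrides>}``."""
    if isinstance(node, TissueProperties):
        return node
    node = dict(node)
    name = node.pop("preset", None)
    if name is not None:
        return preset(name, **node)
    return TissueProperties(**node)


def beam_from_config(node) -> BeamSpec:
    if isinstance(node, BeamSpec):
        return node
    node = dict(node)
    if "diameter_mm" in node:
        node["diameter"] = node.pop("diameter_mm") * 1e-3
    if "pulse_energy_mj" in node:
        node["power_or_energy"] = node.pop("pulse_energy_mj") * 1e-3
        node.setdefault("mode", "pulsed")
    if "power_w" in node:
        node["power_or_energy"] = node.pop("power_w")
        node.setdefault("mode", "continuous")
    return BeamSpec(**node)


def _apply(cfg, data: dict, converters: dict):
    fields = {}
    for key, value in data.items():
        if key in converters:
            fields[key] = converters[key](value)
        else:
            fields[key] = value
    return replace(cfg, **fields)


def depth_attenuation_config(data: dict) -> DepthAttenuationConfig:
    return _apply(DepthAttenuationConfig(), data, {
        "beam": beam_from_config,
        "cover": tissue_from_config,
        "absorber": tissue_from_config,
        "depths_mm": tuple,
    })


def heat_source_recon_config(data: dict) -> HeatSourceReconConfig:
    return _apply(HeatSourceReconConfig(), data, {
        "beam": beam_from_config,
        "background": tissue_from_config,
        "tumor": tissue_from_config,
        "grueneisen": lambda n: GrueneisenModel(**n),
        "extent": tuple,
    })


def ptt_twin_config(data: dict) -> PTTwinConfig:
    return _apply(PTTwinConfig(), data, {
        "beam": beam_from_config,
        "background": tissue_from_config,
        "tumor": tissue_from_config,
        "grueneisen": lambda n: GrueneisenModel(**n),
        "kalman": lambda n: KalmanConfig(**n),
        "extent": tuple,
        "cal_temps": tuple,
    })
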