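"""Shipped default parameters and YAML round-trip.

The defaults here were calibrated once against the qualitative behavior the
model must show (stable attractor bump, velocity-calibrated path
integration, sparse unimodal landmark-bearing tuning, per-environment
remapping) and then frozen.  Every
simulation accepts a ModelConfig so any value can be overridden from code or
from a YAML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .alb import AlbParams
from .core import TransferParams
from .hd_circuit import AttractorSpec

__all__ = ["RscParams", "ModelConfig", "default_config", "direct_config", "load_config", "save_config"]


@dataclass
class RscParams:
    """gRSC/dRSC layer and plasticity parameters.

    gRSC relays the attractor bump under mild self-inhibition; dRSC runs a
    much stronger global competition (g_gi_d) so that only the cells whose
    plastic afferents best match the current HD + landmark input stay
    active.  The landmark projection gain g_in2d is several times the
    gRSC->dRSC gain so that, once associations have formed, the visual scene
    can bias the dRSC bump away from the internal estimate - the lever that
    corrects path-integration drift.  Hebbian rates are slow relative to the
    dwell of the bump at one direction, so rows integrate over many visits
    instead of tracking the most recent one.
    """

    tau: float = 0.02
    transfer_g: TransferParams = field(default_factory=lambda: TransferParams(alpha=0.3, beta=2.0))
    transfer_d: TransferParams = field(default_factory=lambda: TransferParams(alpha=0.45, beta=2.0))
    g_hd2g: float = 1.5
    g_gi_g: float = 1.0
    g_gi_d: float = 8.0
    g_g2d: float = 0.3
    g_in2d: float = 4.0
    w_max: float = 1.0
    w_max_g2d: float = 0.3  # low cap: the internal HD alone barely drives dRSC
    eta_in2d: float = 0.0005
    eta_g2d: float = 0.0005
    init_scale_g2d: float = 0.05
    init_scale_in2d: float = 0.05
    # each dRSC cell carries a weak initial preference for one HD (cells are
    # labelled by these initial preferred directions); the bias anchors the
    # Hebbian competition and makes the fixed 1-to-1 feedback consistent
    init_bias: float = 0.05
    init_bias_kappa: float = 8.0
    norm_mode: str = "cap"


@dataclass
class ModelConfig:
    """Complete parameter set of the two-stage HD model."""

    dt: float = 0.005
    n_vis: int = 360
    target_mean: float = 0.08
    noise_amp: float = 0.0
    noise_kappa: float = 1.0
    attractor: AttractorSpec = field(default_factory=AttractorSpec)
    alb: AlbParams = field(default_factory=AlbParams)
    rsc: RscParams = field(default_factory=RscParams)

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)


def default_config(**overrides) -> ModelConfig:
    """The frozen default configuration, with optional top-level overrides."""
    return ModelConfig(**overrides)


def direct_config(**overrides) -> ModelConfig:
    """Calibrated defaults for the direct visual->dRSC variant.

    The alternative network replaces the sparse landmark-bearing input with
    dense visual channels, so its input gain and Hebbian rate are scaled
    down; everything else matches the full model.
    """
    cfg = ModelConfig(**overrides)
    cfg.rsc.g_in2d = 0.5
    cfg.rsc.eta_in2d = 5e-5
    cfg.rsc.init_scale_in2d = 0.01
    cfg.attractor.g_fb = 0.15  # below the remote-ignition threshold
    return cfg


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    return obj


def _from_dict(cls, data):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) or f.type in (
            "AttractorSpec",
            "AlbParams",
            "RscParams",
            "TransferParams",
        ):
            sub = {
                "AttractorSpec": AttractorSpec,
                "AlbParams": AlbParams,
                "RscParams": RscParams,
                "TransferParams": TransferParams,
            }[f.type if isinstance(f.type, str) else f.type.__name__]
            if isinstance(v, dict):
                if "transfer" in v and isinstance(v["transfer"], dict):
                    v = dict(v, transfer=TransferParams(**v["transfer"]))
                v = sub(**v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _from_dict(ModelConfig, data)
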