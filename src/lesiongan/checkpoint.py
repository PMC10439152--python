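"""Model checkpointing: one archive holding parameters + a config snapshot.

The archive is a NumPy ``.npz`` with every parameter/buffer array plus a JSON
string describing the model kind and its configuration, so a checkpoint is
self-describing and reloads bit-exactly (float32 in, float32 out).
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import numpy as np

from .errors import ConfigurationError

__all__ = ["save_model", "load_model"]


def _config_to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _config_to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_config_to_dict(v) for v in obj]
    return obj


def _model_kind(model) -> str:
    from .discriminator import PatchDiscriminator
    from .egan import EganGenerator
    from .mgan import MganGenerator

    for kind, cls in (("egan", EganGenerator), ("mgan", MganGenerator),
                      ("discriminator", PatchDiscriminator)):
        if isinstance(model, cls):
            return kind
    raise ConfigurationError(f"cannot checkpoint model of type {type(model).__name__}")


def _build_from_config(kind: str, cfg: dict):
    if kind == "egan":
        from .egan import BlockSpec, CompoundScalingSpec, EganConfig, EganGenerator
        cfg = dict(cfg)
        cfg["scaling"] = CompoundScalingSpec(**cfg["scaling"])
        cfg["blocks"] = tuple(BlockSpec(**b) for b in cfg["blocks"])
        cfg["decoder_widths"] = tuple(cfg["decoder_widths"])
        cfg["lateral_sources"] = tuple(cfg["lateral_sources"])
        return EganGenerator(EganConfig(**cfg))
    if kind == "mgan":
        from .mgan import InvertedResidualSpec, MganConfig, MganGenerator
        cfg = dict(cfg)
        cfg["aspp_rates"] = tuple(cfg["aspp_rates"])
        cfg["stages"] = tuple(InvertedResidualSpec(**s) for s in cfg["stages"])
        return MganGenerator(MganConfig(**cfg))
    if kind == "discriminator":
        from .discriminator import DiscriminatorConfig, PatchDiscriminator
        cfg = dict(cfg)
        cfg["widths"] = tuple(cfg["widths"])
        return PatchDiscriminator(DiscriminatorConfig(**cfg))
    raise ConfigurationError(f"unknown checkpoint kind: {kind}")


def save_model(path: str | os.PathLike, model) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"kind": _model_kind(model),
                       "config": _config_to_dict(model.config)})
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    with open(path, "wb") as f:  # exact filename, regardless of extension
        np.savez(f, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)
    return path


def load_model(path: str | os.PathLike):
    path = Path(path)
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model = _build_from_config(meta["kind"], meta["config"])
    model.load_state_dict(state)
    return model
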