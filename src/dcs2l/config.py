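"""YAML configuration loaders for media, head models and grids."""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import yaml

from .datagen import GridSpec
from .forward_models import LayerOptics, TwoLayerMedium
from .mc_head import HeadModel, McLayer


def _as_float(v):
    if isinstance(v, str) and v.strip().lower() in ("inf", "infinity", "∞"):
        return math.inf
    return float(v)


def load_two_layer_medium(path: str | Path) -> TwoLayerMedium:
    """Two-layer medium from a YAML file.

    Expected keys: ``extracerebral`` and ``brain`` mappings (mua, musp, Db,
    thickness) plus top-level rho, beta and optionally wavelength / n0.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    def layer(d, default_thickness=math.inf):
        return LayerOptics(
            mua=_as_float(d["mua"]), musp=_as_float(d["musp"]),
            Db=_as_float(d["Db"]),
            thickness=_as_float(d.get("thickness", default_thickness)))
    kw = {}
    for key in ("rho", "beta", "wavelength", "n0"):
        if key in cfg:
            kw[key] = float(cfg[key])
    return TwoLayerMedium(layer1=layer(cfg["extracerebral"]),
                          layer2=layer(cfg["brain"]), **kw)


def load_head_model(path: str | Path) -> HeadModel:
    """Four-layer head model from a YAML file with a ``layers`` list."""
    cfg = yaml.safe_load(Path(path).read_text())
    layers = tuple(
        McLayer(mua=_as_float(d["mua"]), musp=_as_float(d["musp"]),
                thickness=_as_float(d.get("thickness", math.inf)),
                Db=_as_float(d["Db"]), g=float(d.get("g", 0.89)))
        for d in cfg["layers"])
    kw = {}
    for key in ("n_tissue", "wavelength", "z_max", "r_max"):
        if key in cfg:
            kw[key] = float(cfg[key])
    return HeadModel(layers=layers, **kw)


def load_grid_spec(path: str | Path) -> GridSpec:
    """Training-grid axes from YAML; axes may be lists or {start, stop, num}."""
    cfg = yaml.safe_load(Path(path).read_text())

    def axis(v):
        if isinstance(v, dict):
            return tuple(np.linspace(float(v["start"]), float(v["stop"]),
                                     int(v["num"])))
        return tuple(float(x) for x in v)

    kw = {}
    for key in ("brain_mua", "brain_musp", "thickness", "Db_brain", "extra_fraction"):
        if key in cfg:
            kw[key] = axis(cfg[key])
    for key in ("extra_mua", "extra_musp", "rho", "beta"):
        if key in cfg:
            kw[key] = float(cfg[key])
    return GridSpec(**kw)
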