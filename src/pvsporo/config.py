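"""YAML configuration for full model runs.

A config file has blocks {geometry, materials, bcs, waveform, solver,
outputs}; every entry has a default, so a partial file (or none) works.
``build_model`` turns a config dict into a ready :class:`VasodilationModel`
plus the waveform callable.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .solver import SolverConfig, VasodilationModel
from .waveforms import WaveformSpec

__all__ = ["default_config", "load_config", "dump_config", "build_model"]


def default_config() -> dict:
    return {
        "geometry": {
            "resolution": "desk",        # tiny | desk | fine | workstation
            "fillet_radius_um": 7.0,
        },
        "materials": {
            "mode": "awake",             # awake | sleep
            "k_ecs": None,               # ECS permeability override [m^2]
        },
        "bcs": {
            "P1_mmHg": 0.01,             # SAS driving pressure
            "P0_mmHg": 0.0,
            "inlet": "sas_inlet",        # orientation switch (y=+100)
            "robin_multiplier": 10.0,
        },
        "waveform": {
            "kind": "asymmetric",        # symmetric | asymmetric
            "amplitude_um": 2.0,         # 2 = 20% awake, 4 = 40% sleep
            "period_s": 10.0,
            "T_d_s": None,               # dilation time (None = default)
        },
        "solver": {
            "dt_s": 0.05,
            "T_s": 10.0,
            "n_out": 201,
            "picard_tol": 1e-5,
            "picard_max": 3,
        },
        "outputs": {
            "dir": "scratch/run",
        },
    }


def _merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as f:
            cfg = _merge(cfg, yaml.safe_load(f) or {})
    return cfg


def dump_config(cfg: dict, path):
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def build_model(cfg: dict):
    """(VasodilationModel, WaveformSpec) from a config dict."""
    from dataclasses import replace

    from .bc import RobinOutflowBC
    from .geometry import GeometrySpec

    geo = GeometrySpec(fillet_radius=cfg["geometry"]["fillet_radius_um"])
    solver_cfg = SolverConfig(dt=cfg["solver"]["dt_s"],
                              T=cfg["solver"]["T_s"],
                              n_out=cfg["solver"]["n_out"],
                              picard_tol=cfg["solver"]["picard_tol"],
                              picard_max=cfg["solver"]["picard_max"])
    model = VasodilationModel(
        mode=cfg["materials"]["mode"],
        k_ecs=cfg["materials"]["k_ecs"],
        resolution=cfg["geometry"]["resolution"],
        P1_mmHg=cfg["bcs"]["P1_mmHg"],
        config=solver_cfg, geometry=geo)
    from .bc import SASPressureBC
    model.sas_bc = SASPressureBC(P1_mmHg=cfg["bcs"]["P1_mmHg"],
                                 P0_mmHg=cfg["bcs"]["P0_mmHg"],
                                 inlet=cfg["bcs"]["inlet"],
                                 outlet="sas_outlet"
                                 if cfg["bcs"]["inlet"] == "sas_inlet"
                                 else "sas_inlet")
    model.robin = replace(RobinOutflowBC(),
                          multiplier=cfg["bcs"]["robin_multiplier"])
    wf = WaveformSpec(kind=cfg["waveform"]["kind"],
                      amplitude_um=cfg["waveform"]["amplitude_um"],
                      period=cfg["waveform"]["period_s"],
                      T_d=cfg["waveform"]["T_d_s"])
    return model, wf
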