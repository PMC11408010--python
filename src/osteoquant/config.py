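"""Run configuration: per-modality parameter blocks with defaults and units.

The config file is YAML; unknown keys are rejected so typos fail loudly.
CLI flags override file values.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

#: every parameter has a default and a documented unit
DEFAULTS: dict[str, dict[str, Any]] = {
    "morpho": {
        "margin_um": 200.0,  # peri-implant ROI margin [um]
        "connectivity": 6,  # face connectivity for surface counting
        "days": 61.0,  # implantation time [days]
    },
    "xrf": {
        "ca_threshold_k": 1.0,  # multiplier on the Otsu threshold [-]
        "gd_threshold_k": 1.0,  # multiplier on the Otsu threshold [-]
        "bin_um": 1.0,  # profile bin width [um]
        "max_um": 30.0,  # profile extent from the interface [um]
        "exclusion_um": 0.0,  # near-interface exclusion margin [um]
        "min_area_px": 0,  # small-object removal area [px]
    },
    "scattering": {
        "porod_qmin": 4.5,  # Porod plateau window start [nm^-1]
        "waxs_window_lo": 16.0,  # (002) fit window [nm^-1]
        "waxs_window_hi": 21.0,  # (002) fit window [nm^-1]
        "K": 1.0,  # Scherrer shape factor [-]
    },
    "litm": {
        "visibility_fraction": 0.10,  # implant-channel visibility f [-]
        "percentile": 99.9,  # cutoff percentile [%]
        "ca_fraction": 0.5,  # Ca cutoff fraction [-]
        "p_fraction": 0.5,  # P cutoff fraction [-]
        "fe_fraction": 0.2,  # Fe cutoff fraction [-]
        "band_edges_um": [0.0, 50.0, 150.0],  # interface bands [um]
        "calibration_model": "drift",  # 'static' | 'drift'
    },
    "stages": {  # pipeline stage toggles
        "morpho": True,
        "xrf": True,
        "scattering": True,
        "litm": True,
    },
    "seed": 0,
    "out_dir": "results",
    "log_level": "INFO",
}


@dataclass
class RunConfig:
    values: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def block(self, name: str) -> dict[str, Any]:
        return self.values[name]


def _merge(defaults: Mapping[str, Any], overrides: Mapping[str, Any], path: str = ""):
    out = copy.deepcopy(dict(defaults))
    for key, val in overrides.items():
        where = f"{path}.{key}" if path else key
        if key not in out:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(out[key], dict):
            if not isinstance(val, Mapping):
                raise ValueError(f"config key {where} must be a mapping")
            out[key] = _merge(out[key], val, where)
        else:
            out[key] = val
    return out


def load_config(path: str | None = None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load YAML config over the defaults; ``overrides`` applied last."""
    values = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ValueError(f"{path}: config must be a mapping")
        values = _merge(values, user)
    if overrides:
        values = _merge(values, overrides)
    return RunConfig(values=values)


def dump_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.values, fh, sort_keys=True)
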