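"""Plain-text (YAML) configuration with strict key validation.

Every run of the pipeline resolves its configuration against the defaults
below; unknown keys are rejected so that typos cannot silently fall back
to defaults.  The resolved configuration (including all seeds) is written
next to the outputs of each run.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import numpy as np

from slowmodes.neural_field import ModeBasis, NeuralFieldParams, default_frequency_grid
from slowmodes.synthetic import CohortSpec

__all__ = ["DEFAULTS", "load_config", "resolve", "field_params", "mode_basis", "band_grid", "cohort_spec"]

DEFAULTS: dict = {
    "field": {
        "gamma": 8.0,  # mV
        "tau_ms": 4.0,
        "g0": 2000.0,
        "sigma_mm": 3.0,
        "rho": 0.54,  # 1/mV
        "chi_mv": 30.0,
        "velocity_m_per_s": 3.0,
    },
    "modes": {"kc": 16, "domain_length_mm": 3.0},
    "band": {"omega0_hz": 1.0, "omega_max_hz": 60.0, "df_hz": 0.25},
    "sdcm": {"max_iter": 64, "tol": 0.01, "sub_steps": 8},
    "glm": {"n_harmonics": 16, "lag_scans": 0},
    "bms": {"alpha0": 1.0, "mc_samples": 1_000_000},
    "cohort": {
        "n_subjects": 9,
        "n_regions": 3,
        "n_scans": 700,
        "tr": 3.0,
        "eeg_fs": 250.0,
        "n_eeg_channels": 10,
        "coupling_scale": 0.1,
        "state_noise_sd": 0.05,
        "measurement_snr": 1.0,
        "gsw_amplitude": 1.0,
        "null": False,
    },
    "seed": 42,
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise TypeError(f"config section {here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file and merge it over the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    import yaml

    user = yaml.safe_load(Path(path).read_text()) or {}
    return _merge(DEFAULTS, user)


def resolve(overrides: dict | None = None) -> dict:
    """Resolve a (possibly partial) nested dict of overrides."""
    return _merge(DEFAULTS, overrides or {})


def field_params(cfg: dict) -> NeuralFieldParams:
    f = cfg["field"]
    return NeuralFieldParams(
        gamma=f["gamma"],
        tau=f["tau_ms"] / 1000.0,
        g0=f["g0"],
        sigma=f["sigma_mm"],
        rho=f["rho"],
        chi=f["chi_mv"],
        nu_bar=f["velocity_m_per_s"] * 1000.0,
    )


def mode_basis(cfg: dict) -> ModeBasis:
    return ModeBasis(domain_length=cfg["modes"]["domain_length_mm"], kc=cfg["modes"]["kc"])


def band_grid(cfg: dict) -> np.ndarray:
    b = cfg["band"]
    return default_frequency_grid(b["omega0_hz"], b["omega_max_hz"], b["df_hz"])


def cohort_spec(cfg: dict, **extra) -> CohortSpec:
    c = dict(cfg["cohort"])
    c.update(extra)
    return CohortSpec(seed=cfg["seed"], **c)


def dump_resolved(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg, indent=2, default=float))
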