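"""YAML run-configuration: one file describing design, simulation,
preprocessing and reconstruction parameters.

Sections mirror the library call signatures::

    design:     {matrix: 64, fov: 0.22, radius_frac: 0.25, af: 2, seed: 7, ...}
    simulate:   {scene: derenzo, noise: 0.02, coils: 8, seed: 11, ...}
    preprocess: {water_band: [-60, 60], model_order: 25, smoothing_fwhm: 3.0}
    recon:      {lam: 3.0e-4, rank: 15, outer_iters: 20, ...}

Unknown keys are preserved; missing sections fall back to the defaults
below, so a partial file is valid.
"""

from __future__ import annotations

import copy

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "save_config"]

DEFAULT_CONFIG: dict = {
    "design": {
        "matrix": 64,
        "fov": 0.22,
        "partitions": 1,
        "radius_frac": 0.25,
        "af": 1.0,
        "rosette_fraction": 0.04,
        "sbw": 2280.0,
        "n_time": 500,
        "tr": 0.275,
        "family": "eccentric",
        "seed": 7,
    },
    "simulate": {
        "scene": "derenzo",
        "coils": 8,
        "noise": 0.02,
        "water_scale": 1.0,
        "seed": 11,
    },
    "preprocess": {
        "water_band": [-60.0, 60.0],
        "model_order": 25,
        "smoothing_fwhm": 3.0,
        "magnitude_threshold": 0.05,
        "lp_order": 8,
    },
    "recon": {
        "lam": 3e-4,
        "rank": None,
        "outer_iters": 20,
        "v_cg_iters": 10,
        "u_fista_iters": 15,
        "tgv_inner_iters": 20,
        "alpha_ratio": 2.0,
        "lipid_rank": 8,
        "tol": 1e-4,
        "weighting": "hamming",
    },
}


def load_config(path=None) -> dict:
    """Read a YAML config, merged over :data:`DEFAULT_CONFIG`."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=False)
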