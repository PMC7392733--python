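"""YAML configuration for the pipeline.

One file can carry a ``gkc`` section (CIS-caller parameters), a ``pool``
section (``collapse`` mode), and a ``sim`` section (synthetic-screen
conditions)::

    gkc:
      alpha: 0.001
      n_perm: 1000
      scales: [10000, 20000, 30000]
    pool:
      collapse: within-sample
    sim:
      lambda_bg: 200
      cohort_sizes: {brain: 46, spinal: 50}
"""
from __future__ import annotations

import os

import yaml

from .gkc import GkcParams
from .simulate import SimConfig, config_from_dict


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def load_gkc_params(path: str | os.PathLike) -> GkcParams:
    return GkcParams.from_dict(load_config(path).get("gkc", {}))


def load_sim_config(path: str | os.PathLike) -> SimConfig:
    return config_from_dict(load_config(path).get("sim", {}))


def load_pool_collapse(path: str | os.PathLike) -> str:
    return load_config(path).get("pool", {}).get("collapse", "within-sample")
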