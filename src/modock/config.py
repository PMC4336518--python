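"""YAML run-configuration loading.

A run file has up to four sections, all optional:

.. code-block:: yaml

    scoring:
      dielectric_model: distance_dependent   # or constant
      dielectric_value: 4.0
      lj_table: {C: [0.086, 3.82], N: [0.17, 3.65]}
      empirical_coefficients: [[0,1,1,1,1],[0,1,1,1,1],[0,1,1,1,1]]
      potential_table: potential.txt         # path, relative to the YAML file
    moo: {rho: 1.0e5, lam: 100.0, r_weight: 1.5, update_stride: 1}
    ga:  {n_populations: 4, pop_size: 50, max_generations: 300, seed: 0,
          shrink_factor: 0.8, stall_generations: 50}
    bounds: {padding: 0.0}                   # extra A around the site box
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .ga import GAConfig
from .moo import AggregateConfig
from .pipeline import DockingConfig
from .scoring import EmpiricalCoefficients, ForceFieldParams, read_potential_table

__all__ = ["load_config", "docking_config_from_dict"]


def load_config(path: str | Path) -> DockingConfig:
    path = Path(path)
    data = yaml.safe_load(path.read_text()) or {}
    return docking_config_from_dict(data, base_dir=path.parent)


def docking_config_from_dict(data: dict, base_dir: Path | None = None) -> DockingConfig:
    cfg = DockingConfig()
    sc = data.get("scoring", {})
    ff_kwargs = {}
    if "lj_table" in sc:
        ff_kwargs["lj_table"] = {k: tuple(map(float, v))
                                 for k, v in sc["lj_table"].items()}
    for key in ("dielectric_model", "dielectric_value", "coulomb_factor"):
        if key in sc:
            ff_kwargs[key] = sc[key]
    if ff_kwargs:
        cfg.ff_params = ForceFieldParams(**ff_kwargs)
    if "empirical_coefficients" in sc:
        cfg.emp_coeffs = EmpiricalCoefficients(np.asarray(sc["empirical_coefficients"]))
    if "potential_table" in sc:
        p = Path(sc["potential_table"])
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        cfg.potential = read_potential_table(p.read_text())

    mo = data.get("moo", {})
    cfg.aggregate = AggregateConfig(rho=float(mo.get("rho", 1e5)),
                                    lam=float(mo.get("lam", 100.0)))
    cfg.r_weight = float(mo.get("r_weight", 1.5))
    cfg.update_stride = int(mo.get("update_stride", 1))

    ga_section = data.get("ga", {})
    allowed = {f for f in GAConfig.__dataclass_fields__}
    cfg.ga = GAConfig(**{k: v for k, v in ga_section.items() if k in allowed})

    cfg.bounds_padding = float(data.get("bounds", {}).get("padding", 0.0))
    return cfg
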