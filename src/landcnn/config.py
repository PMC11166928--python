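"""Run configuration: generator parameters with an explicit seed.

A config is a plain mapping persisted as YAML (JSON is valid YAML, so both
work), covering the landscape geometry, per-predictor generator knobs and
the study-design priors.  :func:`landscape_from_config` builds the full
landscape object from it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .experiments import Landscape, make_landscape
from .simulate import StudyDesign

__all__ = ["load_config", "save_config", "landscape_from_config", "design_from_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "landscape": {
        "n_rows": 60,
        "n_cols": 60,
        "n_demes": 39,
        "n_sampled": 9,
        "sample_size_scheme": [18, 9, 7, 6, 4, 3, 2, 2, 1],
        "layer_params": {},
    },
    "design": {
        "n_snps": 4364,
        "split_gen": 21000.0,
        "ancestral_ne_range": [20000.0, 50000.0],
        "deme_size_range": [5.0, 100.0],
        "weight_range": [2.0, 5.0],
        "dispersal_range": [0.1, 0.3],
    },
}


def load_config(path: str | Path) -> dict[str, Any]:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "seed" not in cfg:
        raise ValueError("config must be a mapping with an explicit 'seed' field")
    return cfg


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def landscape_from_config(cfg: dict[str, Any]) -> Landscape:
    lc = cfg.get("landscape", DEFAULT_CONFIG["landscape"])
    return make_landscape(
        n_rows=int(lc["n_rows"]),
        n_cols=int(lc["n_cols"]),
        n_demes=int(lc["n_demes"]),
        n_sampled=int(lc["n_sampled"]),
        sample_size_scheme=list(lc["sample_size_scheme"]),
        seed=int(cfg["seed"]),
        layer_params=lc.get("layer_params") or {},
    )


def design_from_config(cfg: dict[str, Any]) -> StudyDesign:
    dc = dict(DEFAULT_CONFIG["design"])
    dc.update(cfg.get("design", {}))
    lc = cfg.get("landscape", DEFAULT_CONFIG["landscape"])
    return StudyDesign(
        n_demes=int(lc["n_demes"]),
        split_gen=float(dc["split_gen"]),
        ancestral_ne_range=tuple(dc["ancestral_ne_range"]),
        deme_size_range=tuple(dc["deme_size_range"]),
        n_snps=int(dc["n_snps"]),
        weight_range=tuple(dc["weight_range"]),
        dispersal_range=tuple(dc["dispersal_range"]),
    )
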