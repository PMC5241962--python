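"""Flat TOML configuration: detection parameters, normalization and
simulation options.

Layout::

    [detection]
    tau = 0.41503749927884376
    frac = 0.83
    pav_tau = 3.0
    min_probes = 6

    [normalize]
    span = 0.3
    robust_iters = 3
    gc_level = "probe"
    order = ["loess", "gc", "composition"]

    [simulate]
    n_genes = 1000
    # ... any SimConfig field
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any, Dict, Optional, Union

from .model import DetectionParams
from .simulate import SimConfig

PathLike = Union[str, Path]

NORMALIZE_DEFAULTS: Dict[str, Any] = {
    "span": 0.3,
    "robust_iters": 3,
    "gc_level": "probe",
    "order": ["loess", "gc", "composition"],
}


def load_config(path: Optional[PathLike]) -> Dict[str, Any]:
    if path is None:
        return {}
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def detection_params(config: Dict[str, Any], **overrides: Any) -> DetectionParams:
    section = dict(config.get("detection", {}))
    section.update({k: v for k, v in overrides.items() if v is not None})
    return DetectionParams(**section)


def normalize_options(config: Dict[str, Any], **overrides: Any) -> Dict[str, Any]:
    options = dict(NORMALIZE_DEFAULTS)
    options.update(config.get("normalize", {}))
    options.update({k: v for k, v in overrides.items() if v is not None})
    return options


def sim_config(config: Dict[str, Any], **overrides: Any) -> SimConfig:
    section = dict(config.get("simulate", {}))
    section.update({k: v for k, v in overrides.items() if v is not None})
    if "allele_copy_states" in section:
        section["allele_copy_states"] = tuple(section["allele_copy_states"])
    if "dye_bias" in section:
        section["dye_bias"] = tuple(section["dye_bias"])
    return SimConfig(**section)


def _toml_value(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {type(value)} to TOML")


def dump_detection_params(params: DetectionParams, path: PathLike) -> None:
    """Write chosen detection parameters as a config file usable via --config."""
    lines = ["[detection]"]
    for f in dataclasses.fields(params):
        lines.append(f"{f.name} = {_toml_value(getattr(params, f.name))}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
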