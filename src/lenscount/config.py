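"""YAML pipeline configuration with provenance helpers.

A config file has up to three top-level sections::

    simulate:            # LensSimParams fields (angles in *_deg form)
      n_epithelial: 44000
      seed: 1
    analyze:             # AnalysisConfig fields; nested detection params
      anterior_angle_deg: 60
      dna_detect: {min_diameter: 4, max_diameter: 16}
    inputs:              # real-data mode: paths to the four stacks
      anterior_dna: path.tif
      anterior_edu: path.tif
      equatorial_dna: path.tif
      equatorial_edu: path.tif

Angles are degrees in files, radians internally.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from .detect import DetectParams
from .errors import ParameterError
from .io import params_from_dict, params_to_dict
from .pipeline import AnalysisConfig
from .synthetic import LensSimParams

_INPUT_KEYS = {
    "anterior_dna": ("anterior", "dna"),
    "anterior_edu": ("anterior", "edu"),
    "equatorial_dna": ("equatorial", "dna"),
    "equatorial_edu": ("equatorial", "edu"),
}


def analysis_config_from_dict(d: dict) -> AnalysisConfig:
    d = dict(d or {})
    kwargs = {}
    for det_key in ("dna_detect", "edu_detect"):
        if det_key in d:
            kwargs[det_key] = DetectParams(**d.pop(det_key))
    valid = set(AnalysisConfig.__dataclass_fields__)
    for key, value in d.items():
        if key not in valid:
            raise ParameterError(f"unknown analysis parameter {key!r}")
        kwargs[key] = value
    cfg = AnalysisConfig(**kwargs)
    cfg.validate()
    return cfg


def analysis_config_to_dict(cfg: AnalysisConfig) -> dict:
    d = asdict(cfg)
    return d


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    out["simulate"] = params_from_dict(raw.get("simulate", {}) or {})
    out["analyze"] = analysis_config_from_dict(raw.get("analyze", {}) or {})
    inputs = raw.get("inputs")
    if inputs:
        paths: Dict[Tuple[str, str], Path] = {}
        for key, aspect_channel in _INPUT_KEYS.items():
            if key in inputs:
                paths[aspect_channel] = Path(inputs[key])
        out["inputs"] = paths
    return out


def config_hash(params: Optional[LensSimParams], cfg: AnalysisConfig) -> str:
    """Short deterministic hash of the full configuration, for provenance."""
    payload = {
        "simulate": params_to_dict(params) if params is not None else None,
        "analyze": analysis_config_to_dict(cfg),
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
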