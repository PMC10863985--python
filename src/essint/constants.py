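"""Loaders for the versioned score constants and van der Waals radii
shipped as package data (see ``data/score_constants.yaml`` for provenance)."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import yaml


@lru_cache(maxsize=1)
def score_constants() -> dict:
    text = resources.files("essint.data").joinpath("score_constants.yaml").read_text()
    return yaml.safe_load(text)


@lru_cache(maxsize=1)
def vdw_radii() -> dict[str, float]:
    text = resources.files("essint.data").joinpath("vdw_radii.json").read_text()
    doc = json.loads(text)
    return {k: float(v) for k, v in doc.items() if not k.startswith("_")}
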