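"""Model-parameter configuration: YAML/JSON loading and validation.

A config file has one top-level key per model name (liu, klement, ohri,
gucken, santiago); unknown model names or unknown keys inside a model block
are rejected rather than silently ignored.  The shipped default config
carries the published logistic parameters and documented synthetic
placeholder coefficients for the Liu and Klement models, whose original
fitted values are not republished here.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .models import KlementParams, LiuParams, LogisticParams, ModelConfigError

__all__ = ["load_params", "default_config_path", "params_to_dict"]

_LOGISTIC_MODELS = ("ohri", "gucken", "santiago")


def default_config_path() -> Path:
    """Path of the committed default model-parameter config."""
    return Path(str(resources.files("sbrt_tcp").joinpath("data/default_params.yaml")))


def _allowed_fields(cls) -> set:
    return {f.name for f in dataclasses.fields(cls)}


def _build(name: str, block: Mapping) -> object:
    if not isinstance(block, Mapping):
        raise ModelConfigError(f"{name}: expected a mapping of parameters, got {block!r}")
    block = dict(block)
    if name in _LOGISTIC_MODELS:
        cls = LogisticParams
        extra = set(block) - (_allowed_fields(cls) - {"model_name"})
        if extra:
            raise ModelConfigError(f"{name}: unknown config keys {sorted(extra)}")
        return LogisticParams(model_name=name, **block)
    cls = {"liu": LiuParams, "klement": KlementParams}[name]
    extra = set(block) - _allowed_fields(cls)
    if extra:
        raise ModelConfigError(f"{name}: unknown config keys {sorted(extra)}")
    if name == "klement":
        if "eta_coefficients" in block:
            block["eta_coefficients"] = dict(block["eta_coefficients"])
        if block.get("theta_coefficients") is not None:
            block["theta_coefficients"] = dict(block["theta_coefficients"])
        if "binary_covariates" in block:
            block["binary_covariates"] = tuple(block["binary_covariates"])
        if block.get("covariate_refs") is not None:
            block["covariate_refs"] = {
                k: tuple(v) for k, v in dict(block["covariate_refs"]).items()
            }
    return cls(**block)


def load_params(path: str | Path | None = None) -> dict[str, object]:
    """Load a model-parameter config (YAML or JSON) into parameter objects.

    ``None`` loads the committed defaults.  Returns a dict mapping model
    name to its parameter dataclass.
    """
    p = default_config_path() if path is None else Path(path)
    text = p.read_text(encoding="utf-8")
    raw = json.loads(text) if p.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ModelConfigError(f"config {p} must be a mapping of model names")
    known = set(_LOGISTIC_MODELS) | {"liu", "klement"}
    unknown = set(raw) - known
    if unknown:
        raise ModelConfigError(f"unknown model names in config: {sorted(unknown)}")
    return {name: _build(name, block) for name, block in raw.items()}


def params_to_dict(config: Mapping[str, object]) -> dict:
    """JSON-serialisable view of a loaded config (for manifests/hashes)."""
    out = {}
    for name, params in config.items():
        d = dataclasses.asdict(params)
        out[name] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()
        }
    return out
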