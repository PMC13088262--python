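"""Campaign configuration: one structured YAML file describes one
reproducible campaign (space, oracle, initial-data generation, surrogate,
GA and requirement settings).

Every section is optional and defaults to the package's study conditions;
an explicit section overrides field by field.  Validation errors name the
offending field path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import yaml

from .condition_space import ConditionSpace
from .defaults import default_oracle, default_space
from .loop import Requirement
from .oracle import OracleParams
from .proposer import GAConfig

__all__ = ["CampaignConfig", "load_config", "config_hash", "default_config_dict"]

_DATASET_DEFAULTS = {
    "style": "industrial",
    "n": 192,
    "anchor_spread": 0.10,
    "initial_best": 35.5,
    "lab_sigma": 1.0,
}
_SURROGATE_DEFAULTS = {"cv_folds": 5}
_REQUIREMENT_FIELDS = {"target_ct", "conc", "max_rounds"}


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class CampaignConfig:
    space: ConditionSpace
    oracle: OracleParams
    requirement: Requirement
    ga: GAConfig
    datasets: dict
    surrogate: dict
    raw: dict

    def hash(self) -> str:
        return config_hash(self.raw)


def default_config_dict() -> dict:
    return {
        "space": {"preset": "default"},
        "oracle": {"preset": "default"},
        "requirement": {"target_ct": 26.5, "conc": 1e5, "max_rounds": 9},
        "ga": {},
        "datasets": dict(_DATASET_DEFAULTS),
        "surrogate": dict(_SURROGATE_DEFAULTS),
    }


def config_hash(raw: dict) -> str:
    return hashlib.sha256(
        json.dumps(raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _check_keys(section: dict, allowed: set, path: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigError(f"unknown field {path}.{key}")


def load_config(path_or_dict) -> CampaignConfig:
    """Load and validate a campaign config from a YAML path or a dict."""
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        with open(path_or_dict, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    merged = default_config_dict()
    for section, value in raw.items():
        if section not in merged:
            raise ConfigError(f"unknown section {section!r}")
        if not isinstance(value, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        merged[section] = {**merged[section], **value}

    # space
    sspec = merged["space"]
    if "categories" in sspec:
        space = ConditionSpace.from_dict(sspec)
    elif sspec.get("preset", "default") == "default":
        space = default_space()
    else:
        raise ConfigError(f"unknown space.preset {sspec.get('preset')!r}")

    # oracle
    ospec = dict(merged["oracle"])
    if "params" in ospec:
        oracle = OracleParams.from_dict(ospec["params"])
    elif ospec.pop("preset", "default") == "default":
        oracle = default_oracle()
        overridable = {"ct_opt", "noise_sigma_auto", "noise_sigma_hitl", "ref_conc", "slope"}
        _check_keys(ospec, overridable, "oracle")
        if ospec:
            oracle = dataclasses.replace(oracle, **ospec)
    else:
        raise ConfigError(f"unknown oracle.preset")
    if oracle.space.space_id != space.space_id:
        raise ConfigError(
            f"oracle belongs to space {oracle.space.space_id!r}, config space is "
            f"{space.space_id!r}"
        )

    # requirement
    rspec = merged["requirement"]
    _check_keys(rspec, _REQUIREMENT_FIELDS | {"categories_in_scope"}, "requirement")
    if rspec.get("max_rounds", 1) < 1:
        raise ConfigError("requirement.max_rounds must be >= 1")
    try:
        requirement = Requirement(
            target_ct=float(rspec["target_ct"]),
            conc=float(rspec["conc"]),
            max_rounds=int(rspec["max_rounds"]),
            categories_in_scope=(
                tuple(rspec["categories_in_scope"])
                if rspec.get("categories_in_scope")
                else None
            ),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"requirement: {exc}") from exc

    # ga
    gspec = merged["ga"]
    _check_keys(gspec, {f.name for f in dataclasses.fields(GAConfig)}, "ga")
    try:
        ga = GAConfig(**gspec)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"ga: {exc}") from exc

    dspec = merged["datasets"]
    _check_keys(dspec, set(_DATASET_DEFAULTS) | {"seed"}, "datasets")
    if dspec.get("style") not in ("industrial", "literature"):
        raise ConfigError(f"datasets.style must be industrial|literature")
    sgspec = merged["surrogate"]
    _check_keys(sgspec, {"cv_folds"}, "surrogate")

    return CampaignConfig(
        space=space,
        oracle=oracle,
        requirement=requirement,
        ga=ga,
        datasets=dspec,
        surrogate=sgspec,
        raw=merged,
    )
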