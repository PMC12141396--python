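"""Configuration loading: one YAML file drives the whole pipeline.

Sections: ``cohort`` (synthetic-cohort generation), ``matching``,
``efficacy``, ``model`` (the Markov cost-effectiveness engine, with
``arms.tof``/``arms.ada`` subsections) and ``sensitivity`` (tornado + PSA).
Unknown keys anywhere are rejected, so a typo fails loudly instead of
silently running at a default.  The packaged base case lives in
``data/default_config.yaml``.
"""

from __future__ import annotations

import copy
import importlib.resources
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Dict, Optional, Sequence, Union

import yaml

from .cohort import CohortSpec
from .errors import ConfigurationError
from .markov import ArmConfig, ModelConfig, UtilityMap
from .matching import DEFAULT_COVARIATES
from .sensitivity import DEFAULT_TORNADO_PARAMETERS, PSAParameter

__all__ = [
    "load_config",
    "default_config",
    "default_config_path",
    "build_cohort_spec",
    "build_model_config",
    "build_psa_parameters",
    "config_hash",
]

_ARM_KEYS = {
    "drug_cost_per_cycle", "response", "response_counts", "delta_haq",
    "baseline_haq", "haq_progression_per_year", "withdrawal_per_cycle",
    "palliative_drug_cost_per_cycle", "state_cost_base_per_cycle",
    "state_cost_per_haq_per_cycle", "utility", "nonmedical_cost_per_cycle",
    "indirect_cost_per_cycle", "sae_disutility_per_cycle",
}

_SCHEMA: Dict[str, Any] = {
    "cohort": {
        "n_per_arm": None,
        "seed": None,
        "ada_latent_shift": None,
        "response_counts": {"TOF": None, "ADA": None},
    },
    "matching": {"covariates": None, "caliper_sd": None, "order": None},
    "efficacy": {"auxiliary_measures": None},
    "model": {
        "cycle_length": None,
        "horizon": None,
        "start_age": None,
        "end_age": None,
        "discount_rate_costs": None,
        "discount_rate_qalys": None,
        "mortality_per_cycle": None,
        "wtp_per_qaly": None,
        "currency": None,
        "half_cycle_correction": None,
        "arms": {"tof": {k: None for k in _ARM_KEYS},
                 "ada": {k: None for k in _ARM_KEYS}},
    },
    "sensitivity": {
        "tornado": {"parameters": None, "rel_change": None},
        "psa": {"n_iterations": None, "seed": None, "parameters": None},
    },
}


def _check_keys(node: Any, schema: Any, crumb: str = "") -> None:
    if not isinstance(schema, dict) or schema is None or not isinstance(node, dict):
        return
    for key, val in node.items():
        if key not in schema:
            raise ConfigurationError(
                f"unknown configuration key {crumb + key!r}"
            )
        if isinstance(schema[key], dict):
            _check_keys(val, schema[key], crumb + key + ".")


def default_config_path() -> Path:
    return Path(importlib.resources.files("racea") / "data" / "default_config.yaml")


def default_config() -> Dict[str, Any]:
    """The packaged base-case configuration, as a plain dictionary."""
    with open(default_config_path(), "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_config(path: Optional[Union[str, Path]] = None) -> Dict[str, Any]:
    """Load and validate a pipeline configuration (default when no path).

    User files only need the keys they override; everything else falls back
    to the packaged defaults.
    """
    cfg = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        _check_keys(user, _SCHEMA)
        cfg = _merge(cfg, user)
    _check_keys(cfg, _SCHEMA)
    return cfg


def _merge(base: Dict, over: Dict) -> Dict:
    out = copy.deepcopy(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def _response_from_counts(counts: Dict[str, float]) -> Dict[str, float]:
    total = sum(counts.values())
    if total <= 0:
        raise ConfigurationError("response counts must sum to a positive total")
    return {k: v / total for k, v in counts.items()}


def build_cohort_spec(cfg: Dict[str, Any], seed: Optional[int] = None) -> CohortSpec:
    """Cohort spec from the ``cohort`` section (CLI seed override wins)."""
    c = cfg.get("cohort", {})
    spec = CohortSpec()
    if "n_per_arm" in c:
        spec.n_per_arm = int(c["n_per_arm"])
    if "ada_latent_shift" in c:
        spec.ada_latent_shift = float(c["ada_latent_shift"])
    if "response_counts" in c:
        spec.response_probs = {
            arm: _response_from_counts(counts)
            for arm, counts in c["response_counts"].items()
        }
    spec.seed = int(seed if seed is not None else c.get("seed", spec.seed))
    spec.validate()
    return spec


def _build_arm(name: str, a: Dict[str, Any]) -> ArmConfig:
    a = dict(a)
    util = a.pop("utility", {})
    counts = a.get("response_counts")
    if "response" not in a:
        if counts is None:
            raise ConfigurationError(
                f"arm {name}: needs 'response' probabilities or 'response_counts'"
            )
        a["response"] = _response_from_counts(counts)
    try:
        return ArmConfig(name=name, utility=UtilityMap(**util), **a)
    except TypeError as exc:
        raise ConfigurationError(f"arm {name}: {exc}") from exc


def build_model_config(cfg: Dict[str, Any]) -> ModelConfig:
    """Markov model configuration from the ``model`` section."""
    m = dict(cfg.get("model", {}))
    arms_cfg = m.pop("arms", None)
    if not arms_cfg or set(arms_cfg) != {"tof", "ada"}:
        raise ConfigurationError("model.arms must define exactly 'tof' and 'ada'")
    arms = {name: _build_arm(name, sub) for name, sub in arms_cfg.items()}
    try:
        model = ModelConfig(arms=arms, **m)
    except TypeError as exc:
        raise ConfigurationError(f"model: {exc}") from exc
    model.validate()
    return model


def build_psa_parameters(cfg: Dict[str, Any]):
    p = cfg.get("sensitivity", {}).get("psa", {}).get("parameters")
    if p is None:
        return None  # sensible packaged defaults
    try:
        return [PSAParameter(**entry) for entry in p]
    except TypeError as exc:
        raise ConfigurationError(f"sensitivity.psa.parameters: {exc}") from exc


def tornado_parameters(cfg: Dict[str, Any]) -> Sequence[str]:
    return cfg.get("sensitivity", {}).get("tornado", {}).get(
        "parameters", list(DEFAULT_TORNADO_PARAMETERS)
    )


def matching_settings(cfg: Dict[str, Any]) -> Dict[str, Any]:
    m = cfg.get("matching", {})
    return {
        "covariates": m.get("covariates", list(DEFAULT_COVARIATES)),
        "caliper_sd": m.get("caliper_sd", 0.2),
        "order": m.get("order", "descending"),
    }


def config_hash(cfg: Dict[str, Any]) -> str:
    import hashlib

    blob = json.dumps(cfg, sort_keys=True, ensure_ascii=True).encode()
    return hashlib.sha256(blob).hexdigest()
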