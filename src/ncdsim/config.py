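"""Pipeline configuration loading, validation and the run manifest.

A single YAML document configures the whole pipeline (population size,
simulation settings, calibration tolerance, intervention selection,
economics and PSA).  Validation collects every failing field before
raising, so a bad file is reported in one pass.  A run manifest (config
hash, seeds, package version, timestamp) accompanies every set of outputs.
"""

from __future__ import annotations

import copy
import datetime
import hashlib
import json
from importlib import resources

import yaml

from .errors import ConfigurationError

__all__ = ["default_config", "load_config", "dump_config", "validate_config", "make_manifest"]

_KNOWN_IDS = ["1.4", "2.11", "2.13", "3.1", "3.2", "6.2", "6.3", "6.4", "7.3"]


def default_config() -> dict:
    with resources.files("ncdsim.data").joinpath("default_config.yaml").open() as fh:
        return yaml.safe_load(fh)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(cfg: dict) -> None:
    bad = []

    def check(path, pred, msg):
        node = cfg
        try:
            for part in path.split("."):
                node = node[part]
        except (KeyError, TypeError):
            bad.append(f"{path}: missing")
            return
        if not pred(node):
            bad.append(f"{path}: {msg} (got {node!r})")

    check("population.n", lambda v: isinstance(v, int) and v >= 1, "must be a positive integer")
    check("population.lab_observed_fraction", lambda v: 0 <= v <= 1, "must be in [0, 1]")
    check("simulation.horizon_years", lambda v: isinstance(v, int) and v >= 1, "must be >= 1")
    check("simulation.population_size", lambda v: isinstance(v, int) and v >= 1, "must be >= 1")
    check("simulation.discount_rate", lambda v: v >= 0, "must be nonnegative")
    check("simulation.replicates", lambda v: isinstance(v, int) and v >= 1, "must be >= 1")
    check("calibration.tolerance", lambda v: 0 < v < 1, "must be in (0, 1)")
    check("calibration.max_iter", lambda v: isinstance(v, int) and v >= 1, "must be >= 1")
    check("interventions.final_reach", lambda v: 0 <= v <= 1, "must be in [0, 1]")
    check("interventions.selected",
          lambda v: isinstance(v, list) and set(v) <= set(_KNOWN_IDS),
          f"must be a subset of {_KNOWN_IDS}")
    check("economics.gdp_per_capita", lambda v: v > 0, "must be positive")
    check("economics.mode", lambda v: v in ("panel", "simulated"), "must be panel|simulated")
    check("psa.n_draws", lambda v: isinstance(v, int) and v >= 1, "must be >= 1")
    check("seed", lambda v: isinstance(v, int), "must be an integer")
    if bad:
        raise ConfigurationError(
            "configuration invalid:\n  " + "\n  ".join(bad), fields=bad
        )


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load and validate a pipeline configuration; missing fields take the
    shipped defaults (so ``load_config()`` returns the default pipeline)."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    validate_config(cfg)
    return cfg


def dump_config(cfg: dict, path=None) -> str:
    """Canonical YAML serialization (stable key order); round-trips through
    :func:`load_config`."""
    text = yaml.safe_dump(cfg, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:16]


def make_manifest(cfg: dict, stage_seeds: dict, fixtures=None) -> dict:
    from . import __version__

    return {
        "config_hash": config_hash(cfg),
        "master_seed": cfg["seed"],
        "stage_seeds": stage_seeds,
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "fixtures": fixtures or [
            "survey_marginals.yaml", "burden_panel.yaml", "interventions.yaml",
            "risk_coefficients.yaml", "daly_parameters.yaml", "economics.yaml",
        ],
    }


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
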