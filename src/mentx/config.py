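"""Analysis configuration: one YAML file holding every threshold.

All tunable cutoffs (p-value and fold-change thresholds, permutation count,
candidate-filter percentiles, dichotomization rules, the manual candidate
allow-list, seed) live in a single nested mapping with defaults matching
the standard analysis; a user file overrides keys selectively and unknown
keys are rejected.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "normalize": {
        "n_anchors": 14,
        "skip_qspline": False,
    },
    "differential": {
        "p_threshold": 0.01,
        "p_threshold_whoIII": 0.001,
        "fc_threshold": 1.25,
        "n_permutations": 100,
        "fdr_statistic": "median",
    },
    "candidates": {
        "p_primary": 0.01,
        "fc_percentile_high": 90,
        "fc_percentile_low": 10,
        "p_subgroup": 0.01,
        "fc_subgroup": 1.25,
        "min_subgroup_hits": 2,
        "manual_additions": [],
    },
    "clustering": {
        "k": 3,
        "distance": "correlation",
        "linkage": "average",
    },
    "qpcr": {
        "efficiency": 2.0,
        "use_median": False,
        "housekeeping": ["ACTB", "GNB1"],
    },
    "pairs": {
        "fold_up": 2.0,
        "fold_down": 0.5,
        "pairing": "consecutive",
    },
    "survival": {
        "min_followup_months": 36,
        "dichotomize": "median",
        "multivariate_threshold": 0.05,
        "gene_entry_p": 0.001,
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"{here!r} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config merged over the defaults; None -> pure defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    cfg = _merge(DEFAULTS, raw)
    _validate(cfg)
    return cfg


def _validate(cfg: dict[str, Any]) -> None:
    d = cfg["differential"]
    if not (0 < d["p_threshold"] <= 1 and 0 < d["p_threshold_whoIII"] <= 1):
        raise ConfigError("p thresholds must lie in (0, 1]")
    if d["fc_threshold"] <= 1:
        raise ConfigError("fc_threshold must exceed 1")
    if d["n_permutations"] < 1:
        raise ConfigError("n_permutations must be positive")
    if cfg["survival"]["dichotomize"] not in ("median", "upper_quartile", "q75"):
        raise ConfigError("survival.dichotomize must be median or upper_quartile")
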