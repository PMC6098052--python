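"""Package configuration: every numeric default lives in ``defaults.yaml``.

``load_defaults()`` returns a plain nested dict; dataclasses elsewhere pull
their default values from it so that a user can override any constant by
editing one file (or passing an alternative path).
"""
from __future__ import annotations

import copy
import importlib.resources
from functools import lru_cache
from pathlib import Path

import yaml


@lru_cache(maxsize=1)
def _package_defaults() -> dict:
    ref = importlib.resources.files("cmlkinetics").joinpath("defaults.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_defaults(path: str | Path | None = None) -> dict:
    """Load the defaults file (package copy unless *path* is given)."""
    if path is None:
        return copy.deepcopy(_package_defaults())
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def merge_config(base: dict, override: dict | None) -> dict:
    """Recursively merge *override* into a deep copy of *base*."""
    out = copy.deepcopy(base)
    if not override:
        return out
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


DAYS_PER_MONTH: float = _package_defaults()["units"]["days_per_month"]
HOURS_PER_MONTH: float = DAYS_PER_MONTH * 24.0
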