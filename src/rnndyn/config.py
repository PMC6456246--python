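"""Sweep configuration files (YAML or JSON), mirroring EnsembleSpec.

Unknown keys are rejected by name rather than ignored, so a typo in a config
fails loudly before any computation starts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .measures import LyapunovSettings
from .phase import EnsembleSpec

__all__ = ["ConfigError", "load_sweep_config", "dump_sweep_config"]


class ConfigError(ValueError):
    pass


_SPEC_FIELDS = {f.name for f in dataclasses.fields(EnsembleSpec)}
_LYAP_FIELDS = {f.name for f in dataclasses.fields(LyapunovSettings)}
_SEQUENCE_FIELDS = {"balance_values", "density_values", "symmetry_values",
                    "measures"}


def load_sweep_config(path: str | Path) -> EnsembleSpec:
    """Parse and validate a sweep config; defaults fill missing keys."""
    path = Path(path)
    text = path.read_text()
    raw = (json.loads(text) if path.suffix.lower() == ".json"
           else yaml.safe_load(text))
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")

    unknown = set(raw) - _SPEC_FIELDS
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {', '.join(sorted(unknown))}")

    kwargs = dict(raw)
    if "lyapunov" in kwargs:
        lyap = kwargs["lyapunov"]
        if not isinstance(lyap, dict):
            raise ConfigError(f"{path}: 'lyapunov' must be a mapping")
        bad = set(lyap) - _LYAP_FIELDS
        if bad:
            raise ConfigError(
                f"{path}: unknown key(s) under 'lyapunov': {', '.join(sorted(bad))}")
        kwargs["lyapunov"] = LyapunovSettings(**lyap)
    for key in _SEQUENCE_FIELDS & set(kwargs):
        kwargs[key] = tuple(kwargs[key])
    try:
        return EnsembleSpec(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_sweep_config(spec: EnsembleSpec, path: str | Path) -> None:
    """Write a spec back out; ``load_sweep_config`` round-trips it."""
    d = dataclasses.asdict(spec)
    d["lyapunov"] = dataclasses.asdict(spec.lyapunov)
    for key in _SEQUENCE_FIELDS:
        d[key] = [float(v) if key != "measures" else str(v) for v in d[key]]
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
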