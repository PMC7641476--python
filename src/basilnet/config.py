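"""Structured configuration and run manifests.

A run is configured from three layers — package defaults, an optional YAML
config file, and CLI overrides — with later layers winning.  Unknown keys
are rejected with a nearest-valid-key suggestion, and the resolved value of
every parameter is echoed, with its provenance, into a JSON run manifest
alongside content digests of the input files so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .basil_engine import BasilConfig
from .errors import ConfigError

#: keys accepted in a config file / as overrides, beyond BasilConfig fields
_PATH_KEYS = ("bed", "pheno", "pheno_col", "status_col", "covar_cols", "out",
              "val_frac", "test_frac", "lambda_index")
_CONFIG_KEYS = tuple(f.name for f in dataclasses.fields(BasilConfig)) + _PATH_KEYS


def _coerce(key: str, value, target_type):
    if value is None:
        return None
    try:
        if target_type is bool and isinstance(value, str):
            if value.lower() in ("true", "1", "yes"):
                return True
            if value.lower() in ("false", "0", "no"):
                return False
            raise ValueError(value)
        return target_type(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"config key {key!r}: cannot interpret {value!r} "
                          f"as {target_type.__name__}") from exc


def resolve_config(
    config_file=None, cli_overrides: dict | None = None
) -> tuple[BasilConfig, dict, dict]:
    """Merge defaults, config file, and CLI overrides into a BasilConfig.

    The config file is YAML; keys may be flat or grouped under nested
    sections (qc/penalty/basil/output), which are flattened.  Returns
    (BasilConfig, extra path-ish settings, provenance map key -> one of
    "default" / "config_file" / "cli").
    """
    file_values: dict = {}
    if config_file is not None:
        raw = yaml.safe_load(Path(config_file).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a key-value mapping")
        for key, value in raw.items():
            if isinstance(value, dict):  # nested section
                file_values.update(value)
            else:
                file_values[key] = value

    overrides = {k: v for k, v in (cli_overrides or {}).items() if v is not None}

    for source in (file_values, overrides):
        for key in source:
            if key not in _CONFIG_KEYS:
                close = difflib.get_close_matches(key, _CONFIG_KEYS, n=1)
                hint = f"; did you mean {close[0]!r}?" if close else ""
                raise ConfigError(f"unknown config key {key!r}{hint}")

    field_types = {f.name: f.type for f in dataclasses.fields(BasilConfig)}
    base_types = {"family": str, "alpha_mix": float, "n_lambda": int,
                  "lambda_min_ratio": float, "batch_m": int, "delta_m": int,
                  "lambdas_per_iteration": int, "min_pending": int,
                  "kkt_tolerance": float, "early_stop_patience": int,
                  "early_stopping": bool, "max_missing_rate": float,
                  "min_maf": float, "min_batch": int, "relaxed": bool, "seed": int}

    values: dict = {}
    provenance: dict = {}
    extras: dict = {}
    for key in _CONFIG_KEYS:
        if key in overrides:
            val, src = overrides[key], "cli"
        elif key in file_values:
            val, src = file_values[key], "config_file"
        else:
            val, src = None, "default"
        if key in base_types:
            if src != "default":
                values[key] = _coerce(key, val, base_types[key])
            provenance[key] = src
        else:
            if src != "default":
                extras[key] = val
            provenance[key] = src

    try:
        cfg = BasilConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    return cfg, extras, provenance


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written next to every run's outputs."""

    config: dict
    provenance: dict
    input_digests: dict = field(default_factory=dict)
    software_version: str = ""
    iteration_log: list = field(default_factory=list)
    wall_clock: dict = field(default_factory=dict)

    def add_input(self, name: str, path) -> None:
        self.input_digests[name] = {"path": str(path), "sha256": _digest(Path(path))}

    def write(self, path) -> None:
        payload = {
            "software_version": self.software_version,
            "python": platform.python_version(),
            "config": self.config,
            "config_provenance": self.provenance,
            "inputs": self.input_digests,
            "iteration_log": self.iteration_log,
            "wall_clock_seconds": self.wall_clock,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
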