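"""Configuration files, tabular output formats and run manifests.

Configs are TOML with ``[model]``, ``[run]`` and ``[output]`` tables; all
model keys use the :class:`~pomsim.params.ModelParams` field names.
Tabular outputs are tab-separated with a ``#``-prefixed header recording
the generating parameters and seed, so every file reconstructs its
provenance.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .params import ModelParams

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = ["read_config", "write_config", "ConfigError",
           "write_table", "read_table", "write_manifest"]

_RUN_KEYS = {"seed", "t_end", "record_dt", "x_c0", "n_runs",
             "n_interactions", "protocol", "scale", "t_eq",
             "N_bound", "F_ext_list", "x_c_fixed", "bin_s"}
_OUTPUT_KEYS = {"dir", "prefix", "format"}


class ConfigError(ValueError):
    """Raised with the full list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n- " + "\n- ".join(errors))


def read_config(path) -> tuple[ModelParams, dict, dict]:
    """Read and validate a TOML config; returns (params, run, output).

    Unknown keys anywhere and invalid model values are rejected; every
    violation is reported, not just the first.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    errors: list[str] = []
    known_tables = {"model", "run", "output"}
    for key in raw:
        if key not in known_tables:
            errors.append(f"unknown table [{key}]")
    if "model" not in raw:
        errors.append("missing required table [model]")
    model = raw.get("model", {})
    run = raw.get("run", {})
    output = raw.get("output", {})
    field_names = {f.name for f in dataclasses.fields(ModelParams)}
    for key in model:
        if key not in field_names:
            errors.append(f"unknown [model] key {key!r}")
    for key in run:
        if key not in _RUN_KEYS:
            errors.append(f"unknown [run] key {key!r}")
    for key in output:
        if key not in _OUTPUT_KEYS:
            errors.append(f"unknown [output] key {key!r}")
    params = None
    if not errors:
        try:
            params = ModelParams(**model)
        except ValueError as exc:
            errors.extend(str(exc).splitlines()[1:] or [str(exc)])
    if errors:
        raise ConfigError(errors)
    return params, dict(run), dict(output)


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def write_config(params: ModelParams, path, run: dict | None = None,
                 output: dict | None = None) -> None:
    """Write a config file that round-trips through :func:`read_config`."""
    lines = ["[model]"]
    for f in dataclasses.fields(ModelParams):
        lines.append(f"{f.name} = {_toml_value(getattr(params, f.name))}")
    for name, table in (("run", run), ("output", output)):
        if table:
            lines.append("")
            lines.append(f"[{name}]")
            for k, v in table.items():
                lines.append(f"{k} = {_toml_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(frame: pd.DataFrame, path, header: dict | None = None) -> None:
    """Write a TSV with ``# key = value`` provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k} = {v}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV written by :func:`write_table`; returns (frame, header)."""
    header: dict[str, str] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    header[k.strip()] = v.strip()
            else:
                break
    frame = pd.read_csv(path, sep="\t", skiprows=skip)
    return frame, header


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    return obj


def write_manifest(manifest: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonify(manifest), indent=2) + "\n")
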