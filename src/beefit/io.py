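"""Configuration loading and run manifests for the command-line workflow."""

from __future__ import annotations

import datetime
import json
import sys
from pathlib import Path

import yaml

from .errors import InvalidInputError


def load_config(path) -> dict:
    """Load a YAML (or JSON) config mapping.

    If the file is a run manifest, its ``resolved_config`` snapshot is
    returned instead, so a previous run can be replayed directly.
    """
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise InvalidInputError(f"config {path} must be a mapping, got {type(data).__name__}")
    if "resolved_config" in data:
        return data["resolved_config"]
    return data


def write_manifest(path, command: str, resolved_config: dict, artifacts: list) -> None:
    """Record what ran: command, full resolved config (seeds included),
    artifact paths, package/python versions and a timestamp."""
    from . import __version__

    manifest = {
        "command": command,
        "resolved_config": resolved_config,
        "artifacts": [str(a) for a in artifacts],
        "beefit_version": __version__,
        "python_version": sys.version.split()[0],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def check_overwrite(paths, force: bool) -> None:
    existing = [str(p) for p in paths if Path(p).exists()]
    if existing and not force:
        raise InvalidInputError(
            f"refusing to overwrite existing outputs {existing}; pass --force to allow"
        )
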