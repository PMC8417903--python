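"""Run-configuration handling: YAML/JSON round-trips and content hashes.

Analysis drivers load their settings from a YAML or JSON mapping and log
the configuration's content hash together with the seed, so a results
directory can always be traced back to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["load_config", "save_config", "config_hash"]


def load_config(path) -> dict:
    """Read a YAML or JSON mapping (by file extension; YAML reads JSON too)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        out = json.loads(text)
    else:
        out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise ValueError(f"{path} must contain a mapping")
    return out


def save_config(config: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration's canonical JSON form."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
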