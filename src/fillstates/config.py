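"""Run configuration (YAML) and reproducibility manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config; missing path yields an empty config (defaults)."""
    if path is None:
        return {}
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    loaded = yaml.safe_load(p.read_text())
    if loaded is None:
        return {}
    if not isinstance(loaded, dict):
        raise ValueError(f"config must be a YAML mapping, got {type(loaded).__name__}")
    return loaded


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """One manifest per CLI run: config snapshot, input hashes, seeds, version."""

    command: str
    config: dict = field(default_factory=dict)
    seed: int | None = None
    input_hashes: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        if p.is_file():
            self.input_hashes[str(p)] = sha256_file(p)

    def write(self, path: str | Path) -> None:
        from . import __version__

        payload = {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "input_hashes": self.input_hashes,
            "outputs": [str(o) for o in self.outputs],
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str))
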