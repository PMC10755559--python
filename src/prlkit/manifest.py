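"""Run manifests: provenance records written next to every pipeline output."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

MANIFEST_NAME = "manifest.json"


def _hash_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def hash_file(path: str | Path) -> str:
    return _hash_bytes(Path(path).read_bytes())


def write_manifest(out_dir: str | Path, command: str, seeds: dict,
                   config_path: str | Path | None = None,
                   data_paths: dict | None = None,
                   outputs: list | None = None) -> Path:
    """Write a provenance manifest into ``out_dir`` and return its path."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seeds": seeds,
        "config_hash": hash_file(config_path) if config_path else None,
        "data_hashes": {k: hash_file(v) for k, v in (data_paths or {}).items()},
        "outputs": [str(p) for p in (outputs or [])],
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
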