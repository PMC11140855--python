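"""Run manifests: one JSON per output directory recording tool version,
subcommand, resolved parameters, input digests and seed, so deterministic
reruns are verifiable."""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path

from . import __version__

MANIFEST_NAME = "run_manifest.json"


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    subcommand: str,
    params: dict,
    inputs: dict[str, str | Path] | None = None,
    seed: int | None = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "amplimine",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": params,
        "input_digests": {
            name: _digest(p) for name, p in (inputs or {}).items()
        },
        "seed": seed,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    path = out_dir / MANIFEST_NAME
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return path
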