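"""Run manifests: config snapshot, seed, version, input checksums."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

__all__ = ["write_manifest", "sha256_of"]


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    stage: str,
    config: dict,
    seed: int,
    inputs: list | None = None,
    outputs: list | None = None,
) -> Path:
    """Write <stage>.manifest.json next to the stage outputs.

    Checksums cover inputs and produced artifacts so a run can be
    verified as reproducible from its manifest.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "created": datetime.now(timezone.utc).isoformat(),
        "inputs": {str(p): sha256_of(p) for p in (inputs or [])},
        "outputs": {str(p): sha256_of(p) for p in (outputs or [])},
    }
    path = out_dir / f"{stage}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
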