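"""File I/O: multi-page TIFF movies, CSV tables, YAML configs, run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import tifffile
import yaml

__all__ = [
    "save_movie",
    "load_movie",
    "load_yaml",
    "write_manifest",
    "file_sha256",
]


def save_movie(path: str | Path, movie: np.ndarray) -> Path:
    """Write a (frames, h, w) array — or a single 2-D image — as TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))
    return path


def load_movie(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    return out or {}


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: Mapping[str, Any],
    seeds: Mapping[str, int],
    inputs: Mapping[str, str | Path] | None = None,
    counts: Mapping[str, int] | None = None,
    outputs: list[str] | None = None,
) -> Path:
    """Run manifest: config echo, seeds, input hashes, per-stage counts.

    Rerunning with the manifest's config and seeds reproduces the
    outputs of every deterministic stage byte for byte.
    """
    from fadynamics import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "fadynamics",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "platform": platform.platform(),
        "config": dict(config),
        "seeds": dict(seeds),
        "input_hashes": {
            str(k): file_sha256(v) for k, v in (inputs or {}).items()
        },
        "record_counts": dict(counts or {}),
        "outputs": outputs or [],
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path
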