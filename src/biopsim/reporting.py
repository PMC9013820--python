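"""Report writers and run manifests.

Every CLI run writes machine-readable JSON and table-shaped CSV mirrors
of its results into an output directory, alongside a ``manifest.json``
recording the command, configs, seed and package version so any report
can be traced back to the run that produced it.  CSV content is a pure
function of the inputs; only the manifest carries a timestamp.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

__all__ = ["RunManifest", "write_manifest", "write_json", "write_csv"]


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_paths: tuple[str, ...]
    seed: int
    package_version: str
    created_utc: str

    @classmethod
    def create(cls, command: str, seed: int, config_paths=()) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            config_paths=tuple(str(p) for p in config_paths),
            seed=seed,
            package_version=__version__,
            created_utc=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def write_manifest(manifest: RunManifest, out_dir: str | Path) -> Path:
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(_jsonable(manifest), indent=2) + "\n")
    return path


def write_json(payload, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(payload), indent=2) + "\n")
    return path


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False)
    return path
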