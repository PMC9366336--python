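"""File-format plumbing: NIfTI volumes, landmark JSON, CSV tables, manifests.

Landmark files are JSON objects ``{name: [x, y, z]}`` in world mm with the
four canonical names (BA_apex, AICA_origin, VA_fusion, PICA_origin). Every
CLI run writes a JSON manifest recording inputs (with SHA-256 checksums),
parameters and the seed, sufficient to re-run the command identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import LandmarkSet, VoxelGrid

__all__ = ["load_landmarks", "save_landmarks", "load_volume", "save_volume",
           "load_cohort", "save_cohort", "write_manifest", "sha256_of"]


class FormatError(ValueError):
    """Malformed input file; the message names the file and field."""


def load_volume(path) -> VoxelGrid:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: volume file not found")
    try:
        return VoxelGrid.load(path)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable NIfTI volume ({exc})")


def save_volume(grid: VoxelGrid, path) -> None:
    grid.save(path)


def load_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: landmarks file not found")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON in landmarks file ({exc})")
    try:
        return LandmarkSet.from_json_dict(data)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: landmarks: {exc}")


def save_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(json.dumps(landmarks.to_json_dict(), indent=2))


def load_cohort(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: cohort table not found")
    try:
        table = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable CSV ({exc})")
    from .cohort_sim import COHORT_COLUMNS
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: cohort table missing columns {missing}")
    return table


def save_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, inputs: dict, parameters: dict,
                   seed: int | None = None) -> Path:
    """Write ``manifest.json`` describing one pipeline run."""
    from . import __version__

    manifest = {
        "command": command,
        "software": {"name": "bametrics", "version": __version__},
        "seed": seed,
        "inputs": {k: {"path": str(v), "sha256": sha256_of(v)}
                   for k, v in inputs.items() if v is not None},
        "parameters": _jsonable(parameters),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
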