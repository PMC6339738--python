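"""File-format plumbing: meshes, record CSVs, ring CSVs, manifests.

CSV dialect everywhere: comma-separated, UTF-8, "." decimal, mandatory
header row; distances in mm, angles in degrees.  Floats are written with
full repr precision so writer output reads back losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CylgripError
from .grip_metrics import RECORD_COLUMNS
from .landmark_geometry import LandmarkRing

RING_COLUMNS = ["finger", "bone", "end", "point_index", "x_mm", "y_mm", "z_mm"]


def write_mesh(placement, path, fmt: str = "ply", ascii_dialect: bool = False) -> Path:
    """Export a posed bone mesh as PLY or STL (binary or ASCII dialect)."""
    path = Path(path)
    if fmt == "ply":
        data = placement.mesh.export(file_type="ply",
                                     encoding="ascii" if ascii_dialect else "binary")
    elif fmt == "stl":
        data = placement.mesh.export(
            file_type="stl_ascii" if ascii_dialect else "stl")
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def read_mesh(path):
    import trimesh

    try:
        mesh = trimesh.load_mesh(str(path))
    except Exception as e:  # noqa: BLE001 - re-raise with file context
        raise CylgripError(f"malformed mesh file {path}: {e}") from e
    if mesh.is_empty:
        raise CylgripError(f"malformed mesh file {path}: no geometry")
    return mesh


def write_records_csv(records: pd.DataFrame, path) -> Path:
    """Write a long joint-angle table with the canonical header."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise CylgripError(f"records missing columns {missing}")
    path = Path(path)
    records[RECORD_COLUMNS].to_csv(path, index=False, float_format="%.17g")
    return path


def read_records_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise CylgripError(f"{path}: missing columns {missing}")
    return df


def write_rings_csv(rings: dict, path) -> Path:
    """Write ``(finger, bone, end) -> LandmarkRing`` as a flat CSV."""
    rows = []
    for (finger, bone, end), ring in rings.items():
        pts = ring.points if isinstance(ring, LandmarkRing) else np.asarray(ring)
        for i, (x, y, z) in enumerate(pts):
            rows.append((finger, bone, end, i, x, y, z))
    pd.DataFrame(rows, columns=RING_COLUMNS).to_csv(
        Path(path), index=False, float_format="%.17g")
    return Path(path)


def read_rings_csv(path) -> dict:
    df = pd.read_csv(Path(path))
    missing = [c for c in RING_COLUMNS if c not in df.columns]
    if missing:
        raise CylgripError(f"{path}: missing columns {missing}")
    rings = {}
    for (finger, bone, end), g in df.groupby(["finger", "bone", "end"]):
        g = g.sort_values("point_index")
        rings[(finger, bone, end)] = LandmarkRing(
            (finger, bone), end, g[["x_mm", "y_mm", "z_mm"]].to_numpy(float))
    return rings


def write_manifest(path, config, extra: dict | None = None) -> Path:
    """Provenance sidecar: config, seed, and package version."""
    from . import __version__

    payload = {"seed": config.seed, "config": config.to_dict(),
               "cylgrip_version": __version__}
    payload.update(extra or {})
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
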