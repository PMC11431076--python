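"""Readers and writers for the interchange formats.

Cells and cohorts travel as CSV (comma-separated, UTF-8, "." decimal,
header row required); scenes as two single-channel label TIFFs plus a JSON
sidecar carrying um_per_pixel and the class/compartment code tables;
indicators and model reports as JSON.  Every run directory gets a manifest
listing each output file with a SHA-256 content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .scene import COMPARTMENT_CODES, TISSUE_CODES, SegmentationScene

log = logging.getLogger("immunohex")

CELL_COLUMNS = ("x_um", "y_um", "phenotype")


class SchemaError(ValueError):
    """An input file does not match its documented schema."""


def read_cell_table(path, column_map: dict | None = None,
                    um_per_pixel: float | None = None) -> pd.DataFrame:
    """Read a cell-detection CSV into the canonical (x_um, y_um, phenotype) table.

    ``column_map`` renames detector-specific headers onto the canonical
    ones.  When coordinates are in pixel units, pass ``um_per_pixel`` to
    convert.  Rows with non-finite coordinates are rejected (counts logged).
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table {path} is missing columns: {missing}")
    df = df[list(CELL_COLUMNS)].copy()
    finite = np.isfinite(df["x_um"].astype(float)) & np.isfinite(df["y_um"].astype(float))
    dropped = int((~finite).sum())
    if dropped:
        log.warning("dropped %d cell rows with non-finite coordinates", dropped)
    df = df[finite].reset_index(drop=True)
    df["x_um"] = df["x_um"].astype(float)
    df["y_um"] = df["y_um"].astype(float)
    if um_per_pixel is not None:
        df["x_um"] *= um_per_pixel
        df["y_um"] *= um_per_pixel
    if len(df) == 0:
        log.warning("cell table %s is empty", path)
    return df


def write_cell_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    log.info("wrote cell table %s (%d rows)", path, len(df))
    return path


def write_scene(scene: SegmentationScene, directory, stem: str = "scene") -> dict:
    """Write tissue/compartment TIFFs plus a JSON sidecar; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tissue_path = directory / f"{stem}_tissue.tif"
    comp_path = directory / f"{stem}_compartment.tif"
    sidecar_path = directory / f"{stem}_scene.json"
    tifffile.imwrite(tissue_path, scene.tissue)
    tifffile.imwrite(comp_path, scene.compartment)
    sidecar = {
        "um_per_pixel": scene.um_per_pixel,
        "tissue_codes": TISSUE_CODES,
        "compartment_codes": COMPARTMENT_CODES,
        "coordinate_convention": "origin top-left, x rightward, y downward, µm",
        "tissue_raster": tissue_path.name,
        "compartment_raster": comp_path.name,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    for p in (tissue_path, comp_path, sidecar_path):
        log.info("wrote %s", p)
    return {"tissue": tissue_path, "compartment": comp_path, "sidecar": sidecar_path}


def read_scene(sidecar_path) -> SegmentationScene:
    """Read a scene from its JSON sidecar (raster paths resolved relative to it).

    A missing compartment raster is tolerated: the whole slide is then
    treated as tumor compartment (warning logged).
    """
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    if "um_per_pixel" not in meta:
        raise SchemaError(f"sidecar {sidecar_path} lacks required key 'um_per_pixel'")
    base = sidecar_path.parent
    tissue = tifffile.imread(base / meta["tissue_raster"])
    for name, expected in (("tissue_codes", TISSUE_CODES),):
        codes = meta.get(name, expected)
        unknown = set(map(int, codes.values())) - set(expected.values())
        if unknown:
            raise SchemaError(f"unknown {name} values: {sorted(unknown)}")
    if meta.get("compartment_raster"):
        comp = tifffile.imread(base / meta["compartment_raster"])
        if comp.shape != tissue.shape:
            raise SchemaError(
                f"tissue raster {tissue.shape} and compartment raster "
                f"{comp.shape} differ in shape")
    else:
        log.warning("no compartment raster; treating the whole slide as tumor")
        comp = np.full(tissue.shape, COMPARTMENT_CODES["tumor"], dtype=np.uint8)
    return SegmentationScene(tissue=tissue, compartment=comp,
                             um_per_pixel=float(meta["um_per_pixel"]))


def _jsonify(o):
    """Recursively convert numpy scalars/arrays; non-finite floats become null."""
    if isinstance(o, dict):
        return {str(k): _jsonify(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_jsonify(v) for v in o]
    if isinstance(o, np.ndarray):
        return [_jsonify(v) for v in o.tolist()]
    if isinstance(o, (np.integer, int)) and not isinstance(o, bool):
        return int(o)
    if isinstance(o, (np.floating, float)):
        v = float(o)
        return v if np.isfinite(v) else None
    if isinstance(o, (np.bool_,)):
        return bool(o)
    return o


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonify(obj), indent=2, allow_nan=False))
    log.info("wrote %s", path)
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(run_dir, config_dict: dict, files: list, status: str = "ok",
                   failed_stage: str | None = None) -> Path:
    """Manifest for a run directory: config hash, seed, per-file SHA-256."""
    run_dir = Path(run_dir)
    cfg_json = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "status": status,
        "failed_stage": failed_stage,
        "config": config_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config_dict.get("seed"),
        "files": {str(Path(f).relative_to(run_dir)): sha256_of(f)
                  for f in files if Path(f).exists()},
    }
    path = run_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
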