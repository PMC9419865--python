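"""Reading and writing the pipeline's on-disk formats.

Force curves: CSV (columns ``z_um, force_nN, segment``) plus a JSON
metadata sidecar (probe radius, spring constant, region, substrate,
sample id).  Images: TIFF with the pixel size mirrored in a JSON
sidecar.  Ground truth: JSON parameters plus an optional per-object CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile

from .datatypes import ForceCurve, GroundTruth, HeightMap

__all__ = [
    "write_force_curve",
    "read_force_curve",
    "write_image",
    "read_image",
    "write_ground_truth",
    "read_ground_truth",
]


def write_force_curve(curve: ForceCurve, csv_path) -> Path:
    """Write a force curve as CSV + JSON sidecar; returns the CSV path."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {"z_um": curve.z, "force_nN": curve.force, "segment": curve.segment}
    ).to_csv(csv_path, index=False)
    meta = {
        "probe_radius_um": curve.probe_radius,
        "spring_constant_N_per_m": curve.spring_constant,
        "region": curve.region,
        "substrate": curve.substrate_label,
        "sample_id": curve.sample_id,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return csv_path


def read_force_curve(csv_path) -> ForceCurve:
    """Read a CSV + JSON force curve.

    The piezo column may be ``z_um`` or ``z_nm``; the declared unit is
    converted so downstream results are unit-safe.
    """
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    if "z_um" in df.columns:
        z_um = df["z_um"].to_numpy()
    elif "z_nm" in df.columns:
        z_um = df["z_nm"].to_numpy() / 1000.0
    else:
        raise KeyError(f"{csv_path} has neither a z_um nor a z_nm column")
    return ForceCurve(
        z=z_um,
        force=df["force_nN"].to_numpy(),
        segment=df["segment"].to_numpy(),
        probe_radius=meta["probe_radius_um"],
        spring_constant=meta.get("spring_constant_N_per_m", 0.01),
        region=meta.get("region", "cytoplasm"),
        substrate_label=meta.get("substrate", "NCCI"),
        sample_id=meta.get("sample_id", ""),
    )


def write_image(image: np.ndarray, path, pixel_size: float, pixel_unit: str = "um") -> Path:
    """Write an image as TIFF with pixel size in metadata and a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(image, dtype=np.float32),
        metadata={"pixel_size": pixel_size, "pixel_unit": pixel_unit},
    )
    path.with_suffix(".json").write_text(
        json.dumps({"pixel_size": pixel_size, "pixel_unit": pixel_unit})
    )
    return path


def read_image(path) -> Tuple[np.ndarray, Optional[float]]:
    """Read a TIFF; returns (array, pixel_size or None from the sidecar)."""
    path = Path(path)
    arr = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    pixel_size = None
    if sidecar.exists():
        pixel_size = json.loads(sidecar.read_text()).get("pixel_size")
    return arr, pixel_size


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (tuple, list)):
        return [_jsonable(x) for x in v]
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    return v


def write_ground_truth(truth: GroundTruth, stem) -> Path:
    """Write ``<stem>.truth.json`` (+ ``<stem>.truth.csv`` if per-object truth)."""
    stem = Path(stem)
    payload = {"kind": truth.kind, "seed": truth.seed,
               "parameters": _jsonable(truth.parameters)}
    json_path = stem.with_suffix(".truth.json")
    json_path.write_text(json.dumps(payload, indent=2))
    if truth.per_object_truth is not None:
        truth.per_object_truth.to_csv(stem.with_suffix(".truth.csv"), index=False)
    return json_path


def read_ground_truth(stem) -> GroundTruth:
    stem = Path(stem)
    payload = json.loads(stem.with_suffix(".truth.json").read_text())
    csv_path = stem.with_suffix(".truth.csv")
    table = pd.read_csv(csv_path) if csv_path.exists() else None
    return GroundTruth(kind=payload["kind"], parameters=payload["parameters"],
                       seed=payload["seed"], per_object_truth=table)
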