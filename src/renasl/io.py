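"""File I/O: NIfTI images, NPZ series bundles, CSV tables, JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .perfusion import AcquisitionMeta, AslSeries

__all__ = [
    "save_image",
    "load_image",
    "save_series",
    "load_series",
    "save_cohort",
    "load_cohort",
    "load_seeds",
    "save_json",
]

LABEL_LEGEND = {"0": "background", "1": "calyx", "2": "medulla", "3": "cortex"}


def _affine(meta: AcquisitionMeta | None) -> np.ndarray:
    meta = meta or AcquisitionMeta()
    return np.diag([meta.pixel_spacing[0], meta.pixel_spacing[1], meta.slice_thickness, 1.0])


def save_image(path: str | Path, image: np.ndarray, meta: AcquisitionMeta | None = None) -> None:
    """Write a 2-D image (or integer mask) as single-slice NIfTI."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int16)  # nibabel-friendly label dtype
    nib.save(nib.Nifti1Image(arr[..., None], _affine(meta)), str(path))


def load_image(path: str | Path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj)
    return np.squeeze(arr)


def save_series(directory: str | Path, series: AslSeries) -> None:
    """Write one acquisition as an NPZ bundle plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(
        directory / "series.npz",
        m0=series.m0,
        globals_=np.stack([g for g, _ in series.pairs]),
        selectives=np.stack([s for _, s in series.pairs]),
    )
    meta = {
        "inversion_time": series.meta.inversion_time,
        "pixel_spacing": list(series.meta.pixel_spacing),
        "slice_thickness": series.meta.slice_thickness,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_series(directory: str | Path) -> AslSeries:
    directory = Path(directory)
    data = np.load(directory / "series.npz")
    meta_d = json.loads((directory / "meta.json").read_text())
    meta = AcquisitionMeta(
        inversion_time=meta_d["inversion_time"],
        pixel_spacing=tuple(meta_d["pixel_spacing"]),
        slice_thickness=meta_d["slice_thickness"],
    )
    pairs = list(zip(data["globals_"], data["selectives"]))
    return AslSeries(m0=data["m0"], pairs=pairs, meta=meta)


def save_cohort(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_seeds(path: str | Path) -> list[tuple[int, int]]:
    """Seed points as a JSON list of [row, col] pairs."""
    raw = json.loads(Path(path).read_text())
    seeds = [(int(r), int(c)) for r, c in raw]
    if len(seeds) < 3:
        raise ValueError("need at least 3 seed points")
    return seeds


def save_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
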