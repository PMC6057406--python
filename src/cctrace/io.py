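"""File formats: PNG/NIfTI masks, JSON endpoint models, CSV centerlines/labels.

Masks are 8-bit single-channel PNGs (0 background, 255 foreground) with the
physical pixel size in a JSON sidecar (``{"pixel_size_mm": 1.0}``) next to the
image, or 2D NIfTI images whose pixel size comes from the header zooms.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .centerline import Centerline
from .errors import CCTraceError
from .geometry import BinaryMask, Partition
from .shape_context import EndpointModel, LogPolarConfig, ShapeContextHist

MODEL_FORMAT_VERSION = "1"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def read_mask(path, pixel_size_mm: float | None = None,
              flip_x: bool = False, flip_y: bool = False) -> BinaryMask:
    """Load a binary mask from PNG (with optional JSON sidecar) or 2D NIfTI."""
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib
        img = nib.load(str(path))
        arr = np.squeeze(np.asanyarray(img.dataobj))
        if arr.ndim != 2:
            raise CCTraceError(f"{path}: not a 2D image")
        if pixel_size_mm is None:
            pixel_size_mm = float(img.header.get_zooms()[0])
    else:
        arr = np.asarray(Image.open(path).convert("L"))
        if pixel_size_mm is None:
            sidecar = _sidecar(path)
            if sidecar.exists():
                pixel_size_mm = float(
                    json.loads(sidecar.read_text())["pixel_size_mm"])
            else:
                pixel_size_mm = 1.0
    # 0/255 PNG convention vs 0/1 label images
    threshold = 127 if arr.size and arr.max() > 1 else 0
    grid = (arr > threshold).astype(np.uint8)
    if flip_x:
        grid = grid[:, ::-1]
    if flip_y:
        grid = grid[::-1, :]
    return BinaryMask(grid=np.ascontiguousarray(grid),
                      pixel_size_mm=pixel_size_mm)


def write_mask(mask: BinaryMask, path) -> None:
    path = Path(path)
    Image.fromarray((mask.grid * 255).astype(np.uint8), mode="L").save(path)
    _sidecar(path).write_text(
        json.dumps({"pixel_size_mm": mask.pixel_size_mm}) + "\n")


def save_model(model: EndpointModel, path) -> None:
    payload = {
        "format_version": model.format_version,
        "config": model.config.to_dict(),
        "n_training": model.n_training,
        "anterior_hist": model.anterior_hist.bins.ravel().tolist(),
        "posterior_hist": model.posterior_hist.bins.ravel().tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_model(path) -> EndpointModel:
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise CCTraceError(f"unsupported model format version {version!r}")
    config = LogPolarConfig(**payload["config"])
    shape = (config.n_angular, config.n_radial)

    def hist(key):
        return ShapeContextHist(
            bins=np.array(payload[key], float).reshape(shape), config=config)

    return EndpointModel(anterior_hist=hist("anterior_hist"),
                         posterior_hist=hist("posterior_hist"),
                         n_training=int(payload["n_training"]),
                         config=config, format_version=version)


def write_centerline_csv(cl: Centerline, path) -> None:
    pd.DataFrame(cl.points, columns=["x", "y"]).to_csv(path, index=False)


def read_centerline_csv(path, pixel_size_mm: float = 1.0) -> Centerline:
    df = pd.read_csv(path)
    if df.empty:
        raise CCTraceError(f"{path}: empty centerline")
    return Centerline(points=df[["x", "y"]].to_numpy(float),
                      pixel_size_mm=pixel_size_mm)


def write_centerline_json(cl: Centerline, path) -> None:
    Path(path).write_text(json.dumps({
        "pixel_size_mm": cl.pixel_size_mm,
        "points": cl.points.tolist(),
    }) + "\n")


def write_labels_csv(rows, path) -> None:
    """Rows of ``(mask_path, ax, ay, px, py)`` in 0-based pixel coordinates."""
    pd.DataFrame(rows, columns=["mask_path", "ax", "ay", "px", "py"]) \
        .to_csv(path, index=False)


def read_labels_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"mask_path", "ax", "ay", "px", "py"}
    if not required.issubset(df.columns):
        raise CCTraceError(f"{path}: labels CSV needs columns {sorted(required)}")
    return df


def write_partition(partition: Partition, png_path, json_path=None) -> None:
    png_path = Path(png_path)
    Image.fromarray(partition.labels.astype(np.uint8), mode="L").save(png_path)
    meta = {
        "divider_origin": list(map(float, partition.divider_origin)),
        "ray_angles_deg": list(map(float, partition.ray_angles_deg)),
    }
    (Path(json_path) if json_path else _sidecar(png_path)) \
        .write_text(json.dumps(meta) + "\n")
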