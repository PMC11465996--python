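"""File I/O: volumes as multi-page float32 TIFF, 2D images as TIFF/PNG,
metrics as CSV with a JSON parameter sidecar.

Volumes are stored one depth slice per TIFF page (page ``k`` holds the
``(nx, ny)`` plane at depth ``k``), with acquisition metadata (modality,
time point, pixel pitch, source id) embedded in the TIFF description tag and
duplicated in a ``<path>.json`` sidecar.  Round trips are lossless for
float32 data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .reconstruct import EnFaceImage, VolumeStack


class VolumeFormatError(ValueError):
    """Malformed/inconsistent volume file (bad pages, missing metadata)."""


def write_volume(volume: VolumeStack, path: str | Path) -> Path:
    path = Path(path)
    meta = {
        "modality": volume.modality,
        "t": volume.t,
        "pixel_pitch_xy": volume.pixel_pitch_xy,
        "source_id": volume.source_id,
    }
    pages = np.moveaxis(volume.data.astype(np.float32), 2, 0)  # (nz, nx, ny)
    tifffile.imwrite(path, pages, photometric="minisblack", description=json.dumps(meta))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))
    return path


def read_volume(path: str | Path) -> VolumeStack:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {p.shape for p in tif.pages}
            if len(shapes) != 1:
                raise VolumeFormatError(
                    f"{path}: TIFF pages have inconsistent shapes {sorted(shapes)}"
                )
            pages = tif.asarray()
            desc = tif.pages[0].description
    except VolumeFormatError:
        raise
    except Exception as exc:  # corrupt/truncated file
        raise VolumeFormatError(f"{path}: unreadable TIFF volume ({exc})") from exc
    if pages.ndim == 2:
        pages = pages[None]
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    elif desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    for fld in ("modality",):
        if fld not in meta:
            raise VolumeFormatError(f"{path}: metadata field {fld!r} missing")
    data = np.moveaxis(pages, 0, 2)  # back to (nx, ny, nz)
    return VolumeStack(
        data=data,
        modality=meta["modality"],
        t=meta.get("t"),
        pixel_pitch_xy=meta.get("pixel_pitch_xy", 0.01),
        source_id=meta.get("source_id", str(path)),
    )


def write_image(image: EnFaceImage | np.ndarray, path: str | Path) -> Path:
    """Write a 2D image: float32 TIFF for .tif/.tiff, 8-bit PNG preview otherwise."""
    path = Path(path)
    data = image.data if isinstance(image, EnFaceImage) else np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        meta = {}
        if isinstance(image, EnFaceImage):
            meta = {
                "modality": image.modality,
                "projection": image.projection,
                "normalized": image.normalized,
                "pixel_pitch_xy": image.pixel_pitch_xy,
                "parent": image.parent,
            }
        tifffile.imwrite(path, data.astype(np.float32), description=json.dumps(meta))
    else:
        import imageio.v3 as iio

        arr = np.asarray(data, float)
        lo, hi = arr.min(), arr.max()
        arr8 = np.zeros_like(arr) if hi <= lo else (arr - lo) / (hi - lo)
        iio.imwrite(path, (255 * arr8).astype(np.uint8))
    return path


def read_image(path: str | Path) -> EnFaceImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        meta = {}
        if desc:
            try:
                meta = json.loads(desc)
            except json.JSONDecodeError:
                meta = {}
        return EnFaceImage(
            data=data,
            modality=meta.get("modality", ""),
            projection=meta.get("projection", "none"),
            normalized=meta.get("normalized", False),
            pixel_pitch_xy=meta.get("pixel_pitch_xy", 0.01),
            parent=meta.get("parent", str(path)),
        )
    import imageio.v3 as iio

    return EnFaceImage(data=np.asarray(iio.imread(path), float), parent=str(path))


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Binary mask as 8-bit 0/255 TIFF or PNG."""
    return write_image((np.asarray(mask, bool) * 255).astype(np.uint8)
                       if Path(path).suffix.lower() not in (".tif", ".tiff")
                       else np.asarray(mask, np.uint8) * 255, path)


def write_metrics(records, path: str | Path, params: dict | None = None) -> Path:
    """MetricsRecord rows -> CSV, with a JSON sidecar of run parameters."""
    path = Path(path)
    rows = []
    for r in records:
        d = {k: v for k, v in r.__dict__.items() if k != "provenance"}
        d["provenance"] = json.dumps(r.provenance, sort_keys=True)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)
    if params is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(params, indent=2, sort_keys=True, default=str))
    return path


def write_contours(contours, path: str | Path) -> Path:
    """Contour sets as CSV rows (level, contour index, vertex row, vertex col)."""
    path = Path(path)
    rows = []
    for level, polylines in contours:
        for ci, poly in enumerate(polylines):
            for r, c in poly:
                rows.append({"level": level, "contour": ci, "row": r, "col": c})
    pd.DataFrame(rows, columns=["level", "contour", "row", "col"]).to_csv(path, index=False)
    return path
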