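"""En face reconstruction and B-scan utilities for PAM/OCT volumes.

Volumes are amplitude (envelope) data indexed ``(fast-axis x, slow-axis y,
depth z)``.  The modality conventions follow standard practice for these
scanners: photoacoustic en face images are maximum-amplitude projections
(MAP) over depth, OCT en face images are depth-summed intensity projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.signal import hilbert
from skimage import measure

__all__ = [
    "VolumeStack", "EnFaceImage", "BScan",
    "map_projection", "sum_projection", "enface", "normalize",
    "extract_bscan", "extract_roi", "signal_profile", "contour_map",
    "acquisition_time", "envelope",
]


class ShapeError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class VolumeStack:
    """One 3D amplitude volume for a single modality and time point."""

    data: np.ndarray  # (nx, ny, nz)
    modality: str
    t: float | None = None
    pixel_pitch_xy: float = 0.01  # mm / pixel
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"volume must be 3D (nx, ny, nz); got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("volume contains non-finite amplitudes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class EnFaceImage:
    """2D depth-collapsed image with its projection provenance."""

    data: np.ndarray  # (nx, ny)
    modality: str = ""
    projection: Literal["map", "sum", "none"] = "none"
    normalized: bool = False
    pixel_pitch_xy: float = 0.01
    parent: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError(f"en face image must be 2D; got shape {self.data.shape}")


@dataclass
class BScan:
    """Single cross-sectional slice (fast axis x depth) at one slow-axis index."""

    data: np.ndarray  # (nx, nz)
    index: int
    modality: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError(f"B-scan must be 2D; got shape {self.data.shape}")


def envelope(volume: VolumeStack) -> VolumeStack:
    """Analytic-signal magnitude along depth (optional pre-step for RF data)."""
    env = np.abs(hilbert(volume.data, axis=2))
    return replace(volume, data=env)


def map_projection(volume: VolumeStack) -> EnFaceImage:
    """Maximum amplitude projection over depth (PAM en face convention)."""
    if volume.shape[2] < 1:
        raise ShapeError("volume has no depth samples")
    data = np.max(np.abs(volume.data), axis=2)
    return EnFaceImage(data=data, modality=volume.modality, projection="map",
                       pixel_pitch_xy=volume.pixel_pitch_xy, parent=volume.source_id)


def sum_projection(volume: VolumeStack) -> EnFaceImage:
    """Depth-summed intensity projection (OCT en face convention)."""
    if volume.shape[2] < 1:
        raise ShapeError("volume has no depth samples")
    data = np.sum(volume.data, axis=2, dtype=float)
    return EnFaceImage(data=data, modality=volume.modality, projection="sum",
                       pixel_pitch_xy=volume.pixel_pitch_xy, parent=volume.source_id)


def enface(volume: VolumeStack, projection: str | None = None) -> EnFaceImage:
    """Modality-default en face: MAP for PAM, sum for OCT, unless overridden."""
    if projection is None:
        projection = "sum" if volume.modality.startswith("oct") else "map"
    if projection == "map":
        return map_projection(volume)
    if projection == "sum":
        return sum_projection(volume)
    raise ValueError(f"unknown projection {projection!r}; expected 'map' or 'sum'")


def normalize(image: EnFaceImage) -> EnFaceImage:
    """Min-max rescale to [0, 1]; a constant image maps to all zeros.

    The all-zeros convention for constant input keeps downstream thresholding
    well defined (no spurious full-frame foreground).
    """
    if image.data.size == 0:
        raise DataError("cannot normalize an empty image")
    if not np.all(np.isfinite(image.data)):
        raise DataError("image contains non-finite pixels")
    lo = float(image.data.min())
    hi = float(image.data.max())
    if hi > lo:
        data = (image.data - lo) / (hi - lo)
    else:
        data = np.zeros_like(image.data)
    out = replace(image, data=data, normalized=True)
    out.provenance = dict(image.provenance, normalize={"min": lo, "max": hi})
    return out


def extract_bscan(volume: VolumeStack, index: int) -> BScan:
    """B-scan at a zero-based slow-axis index.

    Zero-based: the slice a report calls the "N-th" B-scan is ``index = N-1``.
    """
    ny = volume.shape[1]
    if not 0 <= index < ny:
        raise IndexError(f"B-scan index {index} out of range [0, {ny})")
    return BScan(data=volume.data[:, index, :].copy(), index=index, modality=volume.modality)


def stack_bscans(bscans: list[BScan], volume_template: VolumeStack | None = None) -> np.ndarray:
    """Reassemble (nx, ny, nz) data from a full ordered list of B-scans."""
    return np.stack([b.data for b in bscans], axis=1)


def extract_roi(image: EnFaceImage, origin: tuple[int, int], size: tuple[int, int]) -> EnFaceImage:
    """Crop an (h, w) region of interest with its top-left corner at ``origin``.

    The ROI must lie fully inside the image; there is no clipping.
    """
    r0, c0 = origin
    h, w = size
    nr, nc = image.data.shape
    if h < 1 or w < 1:
        raise ValueError(f"ROI size must be positive, got {size}")
    if r0 < 0 or c0 < 0 or r0 + h > nr or c0 + w > nc:
        raise IndexError(
            f"ROI origin={origin} size={size} exceeds image bounds {(nr, nc)}"
        )
    out = replace(image, data=image.data[r0:r0 + h, c0:c0 + w].copy())
    out.provenance = dict(image.provenance, roi={"origin": [r0, c0], "size": [h, w]})
    return out


def signal_profile(bscan: BScan, depth_range: tuple[int, int] | None = None) -> np.ndarray:
    """Mean amplitude over a depth range, per fast-axis position."""
    nz = bscan.data.shape[1]
    if depth_range is None:
        z0, z1 = 0, nz
    else:
        z0, z1 = depth_range
    if not (0 <= z0 < z1 <= nz):
        raise ValueError(f"invalid depth range ({z0}, {z1}) for nz={nz}")
    return bscan.data[:, z0:z1].mean(axis=1)


def contour_map(bscan: BScan, n_levels: int = 8) -> list[tuple[float, list[np.ndarray]]]:
    """Marching-squares iso-contours at equally spaced levels of a B-scan.

    Returns ``[(level, [polyline, ...]), ...]`` with strictly increasing
    levels placed strictly between the image minimum and maximum.  A constant
    image yields an empty list (there is nothing to contour).
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    lo = float(bscan.data.min())
    hi = float(bscan.data.max())
    if hi <= lo:
        import logging
        logging.getLogger(__name__).warning("contour_map: constant image, no contours")
        return []
    levels = np.linspace(lo, hi, n_levels + 2)[1:-1]
    return [(float(lv), measure.find_contours(bscan.data, lv)) for lv in levels]


def acquisition_time(n_bscans: int, frame_rate: float) -> float:
    """Seconds needed to acquire ``n_bscans`` at ``frame_rate`` B-scans/s."""
    if n_bscans <= 0 or frame_rate <= 0:
        raise ValueError("n_bscans and frame_rate must both be > 0")
    return n_bscans / frame_rate


def acquisition_time_reported(n_bscans: int, frame_rate: float) -> int:
    """Acquisition time rounded to the nearest whole second (reporting helper)."""
    return int(round(acquisition_time(n_bscans, frame_rate)))
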