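"""Vascular extraction: multiscale Hessian vesselness, adaptive-threshold
binarization, morphological cleaning, and topology-preserving thinning.

The stages compose into the standard en-face vessel analysis flow::

    en face image -> vesselness map -> binary mask -> cleaned mask -> skeleton

The vesselness measure is the Frangi tubularity response built from the
eigenvalues of the scale-normalized Gaussian Hessian; thinning is the
Zhang–Suen two-subiteration algorithm, which reduces every vessel to a
one-pixel-wide centerline while preserving connectivity, so skeleton length
is a diameter-independent proxy for total vessel length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage import morphology

from .reconstruct import EnFaceImage

__all__ = [
    "FilterParams", "VesselMaps",
    "frangi_vesselness", "adaptive_threshold", "clean_binary",
    "skeletonize", "extract_vessels",
]


class DataError(ValueError):
    pass


@dataclass
class FilterParams:
    """Tunable parameters of the extraction pipeline.

    ``scales`` are the Gaussian sigmas (pixels) of the multiscale Hessian;
    ``beta`` controls blobness suppression, ``c_mode`` the structureness
    normalization (``"half_max_frobenius"`` sets c per scale to half the
    maximum Hessian Frobenius norm; a float fixes it).  ``gamma`` is the
    scale-normalization exponent of the derivatives (sigma**gamma); 1.5 is
    the ridge-detection choice for which the response of a Gaussian-profile
    ridge of width sigma_true peaks at scale sigma = sigma_true.
    """

    scales: tuple[float, ...] = (1.5, 2.0, 3.0)
    beta: float = 0.5
    c_mode: Literal["half_max_frobenius"] | float = "half_max_frobenius"
    gamma: float = 1.5
    polarity: Literal["bright_on_dark", "dark_on_bright"] = "bright_on_dark"
    threshold_window: int = 15
    threshold_offset: float = 0.08  # fraction of global dynamic range
    #: hysteresis: pixels above the low offset are kept when connected
    #: (within grow_iterations dilation steps) to pixels above the high
    #: offset, recovering the full vessel width without admitting noise.
    threshold_low_offset: float | None = 0.025
    grow_iterations: int = 3
    min_object_px: int = 10
    closing_radius: int = 2
    #: denoising pre-smoothing of the input image (Gaussian sigma, pixels)
    presmooth_sigma: float = 0.8
    #: flat-field (shading) correction: divide by a smoothed fast-axis gain
    #: profile before filtering, compensating the one-sided transducer
    #: sensitivity ramp. None disables.
    shading_sigma: float | None = 16.0

    def __post_init__(self) -> None:
        if len(self.scales) == 0 or any(s <= 0 for s in self.scales):
            raise ValueError("scales must be non-empty and all > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.threshold_window < 3 or self.threshold_window % 2 == 0:
            raise ValueError("threshold_window must be odd and >= 3")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FilterParams":
        d = dict(d)
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        return cls(**d)


@dataclass
class VesselMaps:
    """Linked vesselness / binary mask / skeleton triple for one en face image."""

    vesselness: np.ndarray
    binary: np.ndarray
    skeleton: np.ndarray
    params: FilterParams
    parent: str = ""

    def __post_init__(self) -> None:
        if not (self.vesselness.shape == self.binary.shape == self.skeleton.shape):
            raise ValueError("vesselness, binary and skeleton must share one shape")
        if np.any(self.skeleton & ~self.binary):
            raise ValueError("skeleton must be a subset of the binary mask")


def _hessian_eigenvalues(image: np.ndarray, sigma: float, gamma: float):
    """Eigenvalues (|l1| <= |l2|) of the sigma**gamma-normalized Gaussian Hessian."""
    norm = sigma ** gamma
    hxx = norm * ndimage.gaussian_filter(image, sigma, order=(2, 0), mode="reflect")
    hyy = norm * ndimage.gaussian_filter(image, sigma, order=(0, 2), mode="reflect")
    hxy = norm * ndimage.gaussian_filter(image, sigma, order=(1, 1), mode="reflect")
    # closed-form eigenvalues of the symmetric 2x2 Hessian
    tr2 = 0.5 * (hxx + hyy)
    disc = np.sqrt(((hxx - hyy) * 0.5) ** 2 + hxy ** 2)
    e1 = tr2 + disc
    e2 = tr2 - disc
    swap = np.abs(e1) > np.abs(e2)
    l1 = np.where(swap, e2, e1)  # smaller magnitude
    l2 = np.where(swap, e1, e2)  # larger magnitude
    return l1, l2


def frangi_single_scale(image: np.ndarray, sigma: float, beta: float,
                        c: float | None, gamma: float,
                        polarity: str = "bright_on_dark") -> np.ndarray:
    """Tubularity response at one scale (un-rescaled).

    Response = exp(-Rb^2 / 2 beta^2) * (1 - exp(-S^2 / 2 c^2)) where
    Rb = |l1| / |l2| (blobness) and S = sqrt(l1^2 + l2^2) (structureness,
    equal to the Hessian Frobenius norm), zeroed where l2 has the wrong sign
    for the chosen polarity.  ``c=None`` uses half the maximum S per scale.
    """
    l1, l2 = _hessian_eigenvalues(image, sigma, gamma)
    s2 = l1 ** 2 + l2 ** 2
    if c is None:
        smax = float(np.sqrt(s2.max()))
        c = 0.5 * smax if smax > 0 else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rb2 = np.where(l2 != 0, (l1 / np.where(l2 == 0, 1.0, l2)) ** 2, 0.0)
    resp = np.exp(-rb2 / (2.0 * beta ** 2)) * (1.0 - np.exp(-s2 / (2.0 * c ** 2)))
    wrong_sign = l2 >= 0 if polarity == "bright_on_dark" else l2 <= 0
    resp[wrong_sign] = 0.0
    resp[l2 == 0] = 0.0
    return resp


def frangi_vesselness(image: np.ndarray | EnFaceImage,
                      params: FilterParams | None = None) -> np.ndarray:
    """Multiscale vesselness map in [0, 1]: max over scales, then rescaled."""
    if isinstance(image, EnFaceImage):
        image = image.data
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 8:
        raise DataError(f"image must be 2D and at least 8x8; got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise DataError("image contains non-finite values")
    params = params or FilterParams()
    if image.max() == image.min():
        return np.zeros_like(image)  # no structure at all (avoids eps-noise c)
    c = None if params.c_mode == "half_max_frobenius" else float(params.c_mode)
    out = np.zeros_like(image)
    for sigma in params.scales:
        out = np.maximum(out, frangi_single_scale(
            image, sigma, params.beta, c, params.gamma, params.polarity))
    vmax = out.max()
    if vmax > 0:
        out = out / vmax
    return out


def adaptive_threshold(image: np.ndarray, window: int = 15, offset: float = 0.08,
                       low_offset: float | None = None,
                       grow_iterations: int = 3) -> np.ndarray:
    """Local Gaussian-mean binarization with a global-range additive offset.

    A pixel is foreground iff its value exceeds the Gaussian-weighted local
    mean (window width ``window``, reflective border padding) plus
    ``offset`` times the global dynamic range of the image.

    With ``low_offset`` set, a hysteresis variant is used: the high-offset
    mask seeds a conditional dilation (``grow_iterations`` 8-connected
    steps) constrained to the low-offset mask, so confident centerlines grow
    to the full vessel width while isolated low-contrast pixels stay out.
    """
    image = np.asarray(image, dtype=float)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > min(image.shape):
        raise ValueError(f"window {window} exceeds smallest image dimension {min(image.shape)}")
    sigma = window / 6.0  # +-3 sigma support spans the window
    local_mean = ndimage.gaussian_filter(image, sigma, mode="reflect", truncate=3.0)
    dyn = float(image.max() - image.min())
    high = image > local_mean + offset * dyn
    if low_offset is None:
        return high
    low = image > local_mean + low_offset * dyn
    return ndimage.binary_dilation(high, structure=np.ones((3, 3), bool),
                                   iterations=grow_iterations, mask=low)


def clean_binary(mask: np.ndarray, min_object_px: int = 10, closing_radius: int = 1) -> np.ndarray:
    """Morphological closing followed by small-object removal.

    Closing uses a Chebyshev disk (square footprint of side
    ``2*closing_radius + 1``), so a ``closing_radius`` of 1 bridges
    single-pixel gaps between vessel fragments.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    out = mask
    if closing_radius > 0:
        footprint = np.ones((2 * closing_radius + 1,) * 2, bool)
        out = ndimage.binary_closing(out, structure=footprint, border_value=0)
    if min_object_px > 0:
        labels, n = ndimage.label(out, structure=np.ones((3, 3), int))
        if n:
            sizes = np.bincount(labels.ravel())
            sizes[0] = min_object_px  # background never removed
            out = out & (sizes[labels] >= min_object_px)
    return out


# -- thinning ----------------------------------------------------------------


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Two-subiteration (Zhang–Suen) thinning to unit-width centerlines.

    Deletion decisions within each subiteration are evaluated simultaneously
    on the whole frame, so the result is deterministic with no raster-order
    ties.  Iteration runs to a fixed point, which makes the operation
    idempotent; 8-connectivity and holes of the input are preserved.  Line
    ends erode by roughly half the local width (the usual end effect of
    parallel thinning).
    """
    mask = np.asarray(mask, dtype=bool)
    return morphology.skeletonize(mask, method="zhang")


def flatfield_correct(image: np.ndarray, sigma: float) -> np.ndarray:
    """Divide out a smooth gain field (Gaussian-smoothed background estimate).

    Compensates slowly varying sensitivity such as the lateral falloff away
    from an unfocused transducer, equalizing vessel contrast across the field.
    """
    image = np.asarray(image, dtype=float)
    # the dominant shading is a 1D ramp along the fast axis (transducer
    # side); estimate it per fast-axis row by a low percentile (robust to the
    # bright, sparse vessels) and smooth along the axis
    profile = np.percentile(image, 30, axis=1)
    gain = ndimage.gaussian_filter1d(profile, sigma, mode="reflect")
    floor = 0.05 * float(gain.max()) if gain.max() > 0 else 1.0
    return image / np.maximum(gain, floor)[:, None]


def extract_vessels(image: EnFaceImage | np.ndarray,
                    params: FilterParams | None = None) -> VesselMaps:
    """Full extraction flow: denoise (pre-smooth + flat-field) -> multiscale
    vesselness -> adaptive (hysteresis) threshold -> clean -> skeleton."""
    params = params or FilterParams()
    parent = image.parent if isinstance(image, EnFaceImage) else ""
    data = image.data if isinstance(image, EnFaceImage) else np.asarray(image, float)
    if params.presmooth_sigma > 0:
        data = ndimage.gaussian_filter(data, params.presmooth_sigma, mode="reflect")
    if params.shading_sigma is not None and data.max() > data.min():
        data = flatfield_correct(data, params.shading_sigma)
    v = frangi_vesselness(data, params)
    if v.max() == 0:
        empty = np.zeros(v.shape, bool)
        return VesselMaps(v, empty, empty.copy(), params, parent)
    binary = adaptive_threshold(v, params.threshold_window, params.threshold_offset,
                                params.threshold_low_offset, params.grow_iterations)
    binary = clean_binary(binary, params.min_object_px, params.closing_radius)
    skel = skeletonize(binary)
    return VesselMaps(vesselness=v, binary=binary, skeleton=skel,
                      params=params, parent=parent)
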