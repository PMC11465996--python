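"""Synthetic eye-phantom generator for dual-modality PAM/OCT simulation.

Every downstream stage of the pipeline (reconstruction, vessel extraction,
quantification) is exercised against scenes produced here, for which the
ground truth — vessel centerlines, lesion geometry, contrast-agent kinetics —
is known exactly.  The forward model is deliberately a *projection/attenuation
toy model*, not a wave simulation: photoacoustic amplitude is proportional to
local optical absorption times fluence, OCT amplitude to local backscattering,
each with Beer–Lambert depth attenuation and modality-appropriate noise.

Coordinate convention (used package-wide): arrays are indexed
``(fast-axis x, slow-axis y, depth z)``; the en face plane is ``(x, y)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

Layer = Literal["retinal", "choroidal"]
Modality = Literal["pam532", "pam1064", "oct840"]

MODALITIES: tuple[str, ...] = ("pam532", "pam1064", "oct840")

#: effective Beer-Lambert attenuation length (voxels along depth) per modality.
#: Visible light is absorbed within the retina, so pam532 gets a short length
#: (structures below the RPE fall to near-zero); the 1064 nm and 840 nm bands
#: penetrate the full depth range.
ATTENUATION_LENGTH: dict[str, float] = {
    "pam532": 45.0,
    "pam1064": 600.0,
    "oct840": 600.0,
}


class PhantomParameterError(ValueError):
    """Raised when a phantom parameter violates its stated constraint."""


@dataclass(frozen=True)
class Segment:
    """One straight vessel segment (a capsule when rasterized)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float
    depth_layer: Layer

    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.end, self.start)))


@dataclass
class VesselTree:
    """Connected set of vessel segments grown inside a voxel grid.

    Children start at a parent endpoint, so each root gives one connected
    component.  Geometry is fully determined by ``seed``.
    """

    segments: list[Segment]
    seed: int
    bounding_grid: tuple[int, int, int]

    def __post_init__(self) -> None:
        nx, ny, nz = self.bounding_grid
        for s in self.segments:
            if s.radius < 1.0:
                raise PhantomParameterError(f"segment radius {s.radius} < 1 voxel")
            for p in (s.start, s.end):
                if not (0 <= p[0] <= nx - 1 and 0 <= p[1] <= ny - 1 and 0 <= p[2] <= nz - 1):
                    raise PhantomParameterError(
                        f"segment endpoint {p} outside bounding grid {self.bounding_grid}"
                    )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "bounding_grid": list(self.bounding_grid),
            "segments": [
                {
                    "start": list(s.start),
                    "end": list(s.end),
                    "radius": s.radius,
                    "depth_layer": s.depth_layer,
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VesselTree":
        segs = [
            Segment(tuple(s["start"]), tuple(s["end"]), s["radius"], s["depth_layer"])
            for s in d["segments"]
        ]
        return cls(segments=segs, seed=d["seed"], bounding_grid=tuple(d["bounding_grid"]))


@dataclass
class ContrastAgentModel:
    """Pharmacokinetic toy model of an intravascular dual-contrast agent.

    The agent raises optical absorption (PAM channel) and backscattering
    (OCT channel) of blood proportionally to its concentration.  The blood
    pool signal rises to a peak at ``t_peak`` minutes, then decays
    exponentially with time constant ``tau_decay`` toward
    ``floor_factor`` < 1, so that late time points fall *below* the
    pre-injection baseline.
    """

    concentration: float = 1.0  # mg/mL
    absorption_gain: float = 1.15  # peak fold-change - 1, per (mg/mL)
    scattering_gain: float = 0.083  # per (mg/mL)
    t_peak: float = 2.0  # minutes
    tau_decay: float = 15.0  # minutes
    floor_factor: float = 0.9
    extravasation_fraction: float = 0.3  # share of vascular gain leaking to RPE

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise PhantomParameterError("concentration must be >= 0")
        if self.absorption_gain < 0 or self.scattering_gain < 0:
            raise PhantomParameterError("gains must be >= 0")
        if self.t_peak <= 0:
            raise PhantomParameterError("t_peak must be > 0")
        if self.tau_decay <= 0:
            raise PhantomParameterError("tau_decay must be > 0")
        if not 0.0 <= self.floor_factor <= 1.0:
            raise PhantomParameterError("floor_factor must lie in [0, 1]")


@dataclass
class AcquisitionConfig:
    """Scanner-side parameters of a simulated acquisition."""

    nx: int = 64
    ny: int = 64
    nz: int = 256
    frame_rate: float = 19.5  # B-scans / second
    pulse_energy: float = 90.0  # nJ; PAM amplitude scales linearly with it
    noise_sigma_pam: float = 0.02  # additive Gaussian sigma, amplitude units
    speckle_shape: float = 1.0  # scales OCT speckle variance
    lateral_falloff: float = 0.6  # sensitivity drop from transducer side
    saturation_level: float | None = None  # detector clip (amplitude units); None = off
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "nz"):
            if getattr(self, name) < 8:
                raise PhantomParameterError(f"{name} must be >= 8")
        if self.frame_rate <= 0:
            raise PhantomParameterError("frame_rate must be > 0")
        if self.pulse_energy <= 0:
            raise PhantomParameterError("pulse_energy must be > 0")
        if not 0.0 <= self.lateral_falloff < 1.0:
            raise PhantomParameterError("lateral_falloff must lie in [0, 1)")


@dataclass
class Lesion:
    """Laser-induced CNV-like lesion: saturated core plus neovessel ring."""

    center: tuple[float, float]
    core_radius: float
    ring_outer_radius: float

    def __post_init__(self) -> None:
        if not self.core_radius < self.ring_outer_radius:
            raise PhantomParameterError("lesion radii must satisfy core < ring_outer")


# Per-structure optical coefficients (dimensionless, per wavelength tag).
# Hemoglobin dominates at 532 nm (bright retinal vessels, opaque RPE melanin);
# at 1064 nm melanin in the RPE is the main absorber while blood is weaker,
# and the contrast agent acts on the vascular compartment.
DEFAULT_ABSORPTION: dict[str, float] = {
    "vessel_532": 2.0,
    "vessel_1064": 1.0,
    "rpe_532": 1.2,
    "rpe_1064": 0.6,
    # the laser-induced core is a strong absorber at both wavelengths and
    # protrudes into the subretinal space; under the detector saturation
    # level it renders as a uniform white patch
    "lesion_core_1064": 20.0,
    "lesion_core_532": 20.0,
}
# OCT backscattering: retinal tissue scatters, vessels appear darker than
# their surround, the RPE is the brightest band.
DEFAULT_SCATTERING: dict[str, float] = {
    "retina_slab": 0.30,
    "vessel": 0.15,
    "rpe": 1.0,
    "lesion_core": 1.5,
}


@dataclass
class PhantomScene:
    """Ground-truth scene from which volumes are simulated.

    ``rpe_depth`` is the voxel index of the bright absorbing/scattering layer;
    retinal vessels live above it, choroidal vessels below.
    """

    tree: VesselTree
    rpe_depth: int
    lesion: Lesion | None = None
    absorption_map_params: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ABSORPTION))
    scattering_map_params: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCATTERING))
    agent: ContrastAgentModel | None = None
    #: optional per-segment multiplier on the optical coefficients
    #: (used by tube phantoms, where each tube holds a different concentration)
    segment_scale: list[float] | None = None
    rpe_thickness: int = 6
    retina_top: int | None = None  # top of the scattering retina slab

    def __post_init__(self) -> None:
        nz = self.tree.bounding_grid[2]
        if not 0 <= self.rpe_depth < nz:
            raise PhantomParameterError("rpe_depth must lie inside the grid")
        for d in (self.absorption_map_params, self.scattering_map_params):
            for k, v in d.items():
                if v < 0:
                    raise PhantomParameterError(f"coefficient {k} must be >= 0")
        if self.segment_scale is not None and len(self.segment_scale) != len(self.tree.segments):
            raise PhantomParameterError("segment_scale length must match segment count")

    def to_json(self) -> str:
        d = {
            "tree": self.tree.to_dict(),
            "rpe_depth": self.rpe_depth,
            "lesion": asdict(self.lesion) if self.lesion else None,
            "absorption_map_params": self.absorption_map_params,
            "scattering_map_params": self.scattering_map_params,
            "agent": asdict(self.agent) if self.agent else None,
            "segment_scale": self.segment_scale,
            "rpe_thickness": self.rpe_thickness,
            "retina_top": self.retina_top,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomScene":
        d = json.loads(text)
        lesion = Lesion(tuple(d["lesion"]["center"]), d["lesion"]["core_radius"],
                        d["lesion"]["ring_outer_radius"]) if d.get("lesion") else None
        agent = ContrastAgentModel(**d["agent"]) if d.get("agent") else None
        return cls(
            tree=VesselTree.from_dict(d["tree"]),
            rpe_depth=d["rpe_depth"],
            lesion=lesion,
            absorption_map_params=d["absorption_map_params"],
            scattering_map_params=d["scattering_map_params"],
            agent=agent,
            segment_scale=d.get("segment_scale"),
            rpe_thickness=d.get("rpe_thickness", 6),
            retina_top=d.get("retina_top"),
        )


# --------------------------------------------------------------------------
# vessel-tree growth
# --------------------------------------------------------------------------

_MAX_STEPS_PER_TIP = 24
_MAX_SEGMENTS = 600
_ANGLE_JITTER = 0.25  # rad, per-step heading perturbation
_Z_JITTER = 0.15  # voxels, per-step depth drift
_BRANCH_ANGLE = 0.7  # rad, child heading offset
_RADIUS_SHRINK = 0.8  # child radius factor


def grow_vessel_tree(
    grid: tuple[int, int, int],
    n_roots: int = 3,
    branch_prob: float = 0.12,
    step_len: float = 4.0,
    radius_range: tuple[float, float] = (1.5, 2.5),
    layer: Layer = "retinal",
    seed: int = 0,
    layer_depth: float | None = None,
) -> VesselTree:
    """Grow a random branching vessel tree by a documented stochastic recurrence.

    The growth recurrence, with ``rng = numpy.random.default_rng(seed)`` and a
    LIFO tip stack, consumes random draws in exactly this order:

    1. For each of ``n_roots`` roots (in order): draw ``x0``, ``y0`` uniform on
       ``[margin, n-1-margin]`` (margin = ``step_len + 2``), heading ``theta``
       uniform on ``[0, 2*pi)`` and ``radius`` uniform on ``radius_range``;
       push the tip ``(x0, y0, z_layer, theta, radius)``.
    2. While the stack is non-empty, pop the most recent tip and take up to
       ``_MAX_STEPS_PER_TIP`` steps.  Each step draws, in order:
       ``theta += normal(0, 0.25)``; ``dz = normal(0, 0.15)``; the candidate
       endpoint is ``start + step_len*(cos(theta), sin(theta), 0) + (0,0,dz)``.
       If the endpoint leaves ``[1, n-2]`` in any axis the tip dies (no
       further draws for it).  Otherwise the segment is appended and one more
       draw ``u = uniform()`` decides branching: if ``u < branch_prob`` a final
       draw ``s = uniform()`` picks the child heading sign (+ if ``s < 0.5``)
       and a child tip ``(end, theta +/- 0.7, max(1, 0.8*radius))`` is pushed.
    3. Growth stops when the stack empties or ``_MAX_SEGMENTS`` is reached.

    The recurrence is exact enough to replay independently: a re-run with the
    same stream reproduces the segment list verbatim.
    """
    nx, ny, nz = grid
    if min(nx, ny, nz) < 8:
        raise PhantomParameterError(f"grid dims must all be >= 8, got {grid}")
    if not 0.0 <= branch_prob <= 1.0:
        raise PhantomParameterError(f"branch_prob must lie in [0, 1], got {branch_prob}")
    if radius_range[0] < 1.0:
        raise PhantomParameterError(f"radius_range min must be >= 1, got {radius_range[0]}")
    if n_roots < 1:
        raise PhantomParameterError("n_roots must be >= 1")

    if layer_depth is None:
        layer_depth = 0.3 * nz if layer == "retinal" else 0.62 * nz

    rng = np.random.default_rng(seed)
    margin = step_len + 2.0
    stack: list[tuple[float, float, float, float, float]] = []
    for _ in range(n_roots):
        x0 = rng.uniform(margin, nx - 1 - margin)
        y0 = rng.uniform(margin, ny - 1 - margin)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        radius = rng.uniform(*radius_range)
        stack.append((x0, y0, float(layer_depth), theta, radius))

    segments: list[Segment] = []
    while stack and len(segments) < _MAX_SEGMENTS:
        x, y, z, theta, radius = stack.pop()
        for _ in range(_MAX_STEPS_PER_TIP):
            theta += rng.normal(0.0, _ANGLE_JITTER)
            dz = rng.normal(0.0, _Z_JITTER)
            ex = x + step_len * math.cos(theta)
            ey = y + step_len * math.sin(theta)
            ez = z + dz
            if not (1 <= ex <= nx - 2 and 1 <= ey <= ny - 2 and 1 <= ez <= nz - 2):
                break
            segments.append(Segment((x, y, z), (ex, ey, ez), radius, layer))
            if len(segments) >= _MAX_SEGMENTS:
                break
            u = rng.uniform()
            if u < branch_prob:
                s = rng.uniform()
                sign = 1.0 if s < 0.5 else -1.0
                stack.append((ex, ey, ez, theta + sign * _BRANCH_ANGLE,
                              max(1.0, _RADIUS_SHRINK * radius)))
            x, y, z = ex, ey, ez

    return VesselTree(segments=segments, seed=seed, bounding_grid=grid)


# --------------------------------------------------------------------------
# rasterization
# --------------------------------------------------------------------------


def _capsule_mask(shape: tuple[int, ...], seg: Segment, enface: bool) -> np.ndarray:
    """Boolean mask of voxels (or pixels) within ``seg.radius`` of the centerline."""
    a = np.asarray(seg.start, float)
    b = np.asarray(seg.end, float)
    r = seg.radius
    ndim = 2 if enface else 3
    if enface:
        a, b = a[:2], b[:2]
    lo = np.maximum(np.floor(np.minimum(a, b) - r).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(a, b) + r).astype(int) + 1, shape[:ndim])
    if np.any(lo >= hi):
        return np.zeros(0, bool)  # degenerate, outside grid
    grids = np.meshgrid(*(np.arange(lo[i], hi[i]) for i in range(ndim)), indexing="ij")
    pts = np.stack([g.astype(float) for g in grids], axis=-1)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    sub = dist2 <= r * r
    out = np.zeros(shape[:ndim], bool)
    out[tuple(slice(lo[i], hi[i]) for i in range(ndim))] = sub
    return out


def rasterize_tree(tree: VesselTree, mode: Literal["mask3d", "enface_mask"] = "mask3d") -> np.ndarray:
    """Rasterize a vessel tree as a capsule union.

    ``mask3d`` marks every voxel within a segment's radius of its centerline;
    ``enface_mask`` is the depth-collapse (logical any over z) of that volume,
    computed directly in 2D.
    """
    if mode not in ("mask3d", "enface_mask"):
        raise PhantomParameterError(f"unknown rasterization mode {mode!r}")
    nx, ny, nz = tree.bounding_grid
    shape = (nx, ny, nz)
    out_shape = (nx, ny) if mode == "enface_mask" else shape
    out = np.zeros(out_shape, bool)
    if not tree.segments:
        logger.warning("rasterize_tree called on an empty tree; returning all-false mask")
        return out
    for seg in tree.segments:
        m = _capsule_mask(shape, seg, enface=(mode == "enface_mask"))
        if m.size:
            out |= m
    return out


def centerline_enface_mask(tree: VesselTree) -> np.ndarray:
    """En face ground-truth centerline map (1-px polylines of all segments)."""
    nx, ny, _ = tree.bounding_grid
    out = np.zeros((nx, ny), bool)
    for seg in tree.segments:
        n = max(2, int(math.ceil(seg.length() * 2)))
        ts = np.linspace(0.0, 1.0, n)
        xs = np.clip(np.round(seg.start[0] + ts * (seg.end[0] - seg.start[0])).astype(int), 0, nx - 1)
        ys = np.clip(np.round(seg.start[1] + ts * (seg.end[1] - seg.start[1])).astype(int), 0, ny - 1)
        out[xs, ys] = True
    return out


# --------------------------------------------------------------------------
# tube phantom
# --------------------------------------------------------------------------

#: gains used for *tube* phantoms, chosen so that simulated tube measurements
#: reproduce the bench calibration: PAM amplitude at 1.0 mg/mL is ~144.6 % of
#: saline, and OCT scattering at 1.0 mg/mL is ~3.5-fold saline.
TUBE_ABSORPTION_GAIN = 0.446  # per mg/mL
TUBE_SCATTERING_GAIN = 2.5  # per mg/mL


def build_tube_phantom(
    concentrations: Sequence[float],
    tube_inner_radius: float = 3.0,
    grid: tuple[int, int, int] = (64, 64, 64),
    absorption_gain: float = TUBE_ABSORPTION_GAIN,
    scattering_gain: float = TUBE_SCATTERING_GAIN,
) -> PhantomScene:
    """Parallel-tube calibration phantom, one tube per agent concentration.

    Tubes run along the slow axis at mid depth, equally spaced across the fast
    axis.  Each tube's absorption/scattering coefficients scale linearly with
    concentration through the agent gains; saline is encoded as 0.0 mg/mL.
    """
    concs = list(concentrations)
    if any(c < 0 for c in concs):
        raise PhantomParameterError("concentrations must be >= 0 (saline = 0.0)")
    nx, ny, nz = grid
    n = len(concs)
    spacing = nx / (n + 1)
    if spacing <= 2 * tube_inner_radius:
        raise PhantomParameterError(
            f"tubes of radius {tube_inner_radius} overlap at spacing {spacing:.1f}; "
            "use a wider grid or fewer tubes"
        )
    z_mid = nz / 2.0
    segments = [
        Segment((spacing * (i + 1), 1.0, z_mid), (spacing * (i + 1), ny - 2.0, z_mid),
                tube_inner_radius, "retinal")
        for i in range(n)
    ]
    tree = VesselTree(segments=segments, seed=0, bounding_grid=grid)
    # baseline (saline) coefficient 1.0 per channel; agent adds linear gain
    scale = [1.0 + absorption_gain * c for c in concs]
    scene = PhantomScene(
        tree=tree,
        rpe_depth=nz - 2,  # no RPE band inside the tube region
        absorption_map_params={"vessel_532": 1.0, "vessel_1064": 1.0,
                               "rpe_532": 0.0, "rpe_1064": 0.0},
        scattering_map_params={"retina_slab": 0.0, "vessel": 1.0, "rpe": 0.0},
        segment_scale=scale,
        rpe_thickness=1,
        retina_top=None,
    )
    # stash the scattering scale for simulate_volume's OCT channel
    scene.scattering_segment_scale = [1.0 + scattering_gain * c for c in concs]  # type: ignore[attr-defined]
    scene.tube_concentrations = concs  # type: ignore[attr-defined]
    return scene


# --------------------------------------------------------------------------
# contrast-agent kinetics
# --------------------------------------------------------------------------


def contrast_timecourse(
    agent: ContrastAgentModel,
    t: float | np.ndarray,
    channel: Literal["absorption", "scattering"] = "absorption",
) -> float | np.ndarray:
    """Multiplicative enhancement factor of the blood-pool signal at time ``t``.

    Piecewise rise/decay form: the factor is 1 at t=0, rises linearly to its
    peak ``1 + gain * concentration`` at ``t_peak``, then relaxes
    exponentially (time constant ``tau_decay``) toward
    ``floor_factor`` < 1, reproducing the observed early saturation and the
    sub-baseline signal at the end of a one-hour series.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise PhantomParameterError("time must be >= 0 minutes")
    gain = agent.absorption_gain if channel == "absorption" else agent.scattering_gain
    peak = 1.0 + gain * agent.concentration
    rise = 1.0 + (peak - 1.0) * (t_arr / agent.t_peak)
    decay = agent.floor_factor + (peak - agent.floor_factor) * np.exp(
        -(t_arr - agent.t_peak) / agent.tau_decay
    )
    out = np.where(t_arr <= agent.t_peak, rise, decay)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


# --------------------------------------------------------------------------
# forward simulation
# --------------------------------------------------------------------------


def _lateral_ramp(nx: int, falloff: float) -> np.ndarray:
    """Linear sensitivity ramp: 1.0 at the transducer side to 1-falloff."""
    return np.linspace(1.0, 1.0 - falloff, nx)


def _structure_masks(scene: PhantomScene) -> dict[str, np.ndarray]:
    nx, ny, nz = scene.tree.bounding_grid
    masks: dict[str, np.ndarray] = {}
    rpe = np.zeros((nx, ny, nz), bool)
    z0 = scene.rpe_depth
    z1 = min(nz, z0 + scene.rpe_thickness)
    rpe[:, :, z0:z1] = True
    masks["rpe"] = rpe
    if scene.retina_top is not None:
        slab = np.zeros((nx, ny, nz), bool)
        slab[:, :, scene.retina_top:z0] = True
        masks["retina_slab"] = slab
    if scene.lesion is not None:
        cx, cy = scene.lesion.center
        X, Y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        core2d = (X - cx) ** 2 + (Y - cy) ** 2 <= scene.lesion.core_radius ** 2
        core = np.zeros((nx, ny, nz), bool)
        z_top = scene.retina_top if scene.retina_top is not None else max(0, z0 - 3)
        core[:, :, z_top:z1] = core2d[:, :, None]  # protrudes into subretinal space
        masks["lesion_core"] = core
        r2 = (X - cx) ** 2 + (Y - cy) ** 2
        ring2d = (r2 > scene.lesion.core_radius ** 2) & (
            r2 <= scene.lesion.ring_outer_radius ** 2
        )
        ring = np.zeros((nx, ny, nz), bool)
        ring[:, :, max(0, z0 - 3):z0] = ring2d[:, :, None]  # neovessels just above RPE
        masks["lesion_ring"] = ring
    return masks


def simulate_volume(
    scene: PhantomScene,
    config: AcquisitionConfig,
    modality: Modality,
    t: float = 0.0,
):
    """Simulate one amplitude volume for a scene at time ``t`` minutes.

    PAM voxel amplitude = pulse-energy scale x local absorption (wavelength
    tagged) x Beer-Lambert depth attenuation x lateral sensitivity ramp,
    plus additive zero-mean Gaussian noise.  OCT amplitude = local
    backscattering x depth attenuation x multiplicative Rayleigh speckle.
    The contrast-agent factor multiplies the vascular compartment, and a
    fraction of the vascular gain leaks into the RPE band after injection
    (extravasation).  Deterministic given ``config.seed``.
    """
    from .reconstruct import VolumeStack  # local import to avoid a cycle

    if modality not in MODALITIES:
        raise PhantomParameterError(
            f"unknown modality {modality!r}; expected one of {MODALITIES}"
        )
    nx, ny, nz = scene.tree.bounding_grid
    if (config.nx, config.ny, config.nz) != (nx, ny, nz):
        raise PhantomParameterError(
            f"config grid {(config.nx, config.ny, config.nz)} does not match scene grid {(nx, ny, nz)}"
        )
    rng = np.random.default_rng(config.seed)
    wl = "532" if modality == "pam532" else "1064"
    masks = _structure_masks(scene)

    agent = scene.agent
    f_abs = contrast_timecourse(agent, t, "absorption") if agent else 1.0
    f_scat = contrast_timecourse(agent, t, "scattering") if agent else 1.0

    vessel_mask = np.zeros((nx, ny, nz), bool)
    coeff_abs = np.zeros((nx, ny, nz))
    coeff_scat = np.zeros((nx, ny, nz))
    abs_p = scene.absorption_map_params
    scat_p = scene.scattering_map_params
    scat_scale = getattr(scene, "scattering_segment_scale", None)
    for i, seg in enumerate(scene.tree.segments):
        m = _capsule_mask((nx, ny, nz), seg, enface=False)
        if not m.size:
            continue
        vessel_mask |= m
        a_scale = scene.segment_scale[i] if scene.segment_scale else 1.0
        s_scale = scat_scale[i] if scat_scale else a_scale
        coeff_abs[m] = abs_p.get(f"vessel_{wl}", 0.0) * a_scale
        coeff_scat[m] = scat_p.get("vessel", 0.0) * s_scale

    if "retina_slab" in masks:
        slab = masks["retina_slab"] & ~vessel_mask
        coeff_scat[slab] = scat_p.get("retina_slab", 0.0)
    rpe = masks["rpe"] & ~vessel_mask
    coeff_abs[rpe] = abs_p.get(f"rpe_{wl}", 0.0)
    coeff_scat[rpe] = scat_p.get("rpe", 0.0)
    if "lesion_core" in masks:
        core = masks["lesion_core"]
        coeff_abs[core] = abs_p.get(f"lesion_core_{wl}", 0.0)
        coeff_scat[core] = scat_p.get("lesion_core", 0.0)
        ring = masks["lesion_ring"] & ~vessel_mask
        coeff_abs[ring] = 0.8 * abs_p.get(f"vessel_{wl}", 0.0)
        coeff_scat[ring] = scat_p.get("vessel", 0.0)
        vessel_mask |= masks["lesion_ring"]  # neovessels carry agent too

    # contrast agent: vascular compartment plus RPE extravasation after t=0
    if agent is not None and scene.segment_scale is None:
        coeff_abs[vessel_mask] *= f_abs
        coeff_scat[vessel_mask] *= f_scat
        if t > 0 and agent.extravasation_fraction > 0:
            leak = 1.0 + agent.extravasation_fraction * (f_abs - 1.0)
            coeff_abs[rpe] *= max(leak, 0.0)

    z = np.arange(nz, dtype=float)
    atten = np.exp(-z / ATTENUATION_LENGTH[modality])[None, None, :]
    if modality.startswith("pam"):
        ramp = _lateral_ramp(nx, config.lateral_falloff)[:, None, None]
        data = (config.pulse_energy / 90.0) * coeff_abs * atten * ramp
        if config.noise_sigma_pam > 0:
            data = data + rng.normal(0.0, config.noise_sigma_pam, data.shape)
        if config.saturation_level is not None:
            # detector saturation: over-threshold regions (e.g. the lesion
            # core) clip to a uniform white level
            data = np.minimum(data, config.saturation_level)
    else:
        data = coeff_scat * atten
        if config.speckle_shape > 0:
            # Rayleigh speckle scaled to unit mean
            sigma_r = config.speckle_shape / math.sqrt(math.pi / 2.0)
            data = data * rng.rayleigh(sigma_r, data.shape)
    return VolumeStack(
        data=data.astype(np.float32),
        modality=modality,
        t=t,
        pixel_pitch_xy=0.01,
        source_id=f"phantom-seed{scene.tree.seed}-acq{config.seed}",
    )


def build_fundus_scene(
    grid: tuple[int, int, int] = (64, 64, 256),
    seed: int = 0,
    with_choroid: bool = True,
    lesion: Lesion | None = None,
    agent: ContrastAgentModel | None = None,
    n_roots: int = 3,
    branch_prob: float = 0.12,
    radius_range: tuple[float, float] = (1.5, 2.5),
) -> PhantomScene:
    """Canonical two-layer fundus scene: retinal tree over an RPE band, with an
    optional choroidal tree beneath it and optional lesion/agent."""
    nx, ny, nz = grid
    rpe_depth = int(0.5 * nz)
    retinal = grow_vessel_tree(grid, n_roots=n_roots, branch_prob=branch_prob,
                               radius_range=radius_range, layer="retinal", seed=seed,
                               layer_depth=0.3 * nz)
    segments = list(retinal.segments)
    if with_choroid:
        choroidal = grow_vessel_tree(grid, n_roots=n_roots, branch_prob=branch_prob,
                                     radius_range=radius_range, layer="choroidal",
                                     seed=seed + 1000, layer_depth=0.62 * nz)
        segments += choroidal.segments
    tree = VesselTree(segments=segments, seed=seed, bounding_grid=grid)
    return PhantomScene(
        tree=tree,
        rpe_depth=rpe_depth,
        lesion=lesion,
        agent=agent,
        retina_top=int(0.2 * nz),
    )
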