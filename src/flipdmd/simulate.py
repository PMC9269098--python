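"""Synthetic FLIP image-stack simulator.

Renders multi-frame stacks of a cell with a nucleus, cytoplasm, circular
protein aggregates and a circular bleach region, following the
three-compartment kinetics of :mod:`flipdmd.compartment`: each pixel
carries the intensity of the compartment it belongs to, evaluated at the
frame time. Options add an unbleached neighboring cell (constant
intensity), Brownian or directed (flow) motion of one aggregate, and
Gaussian or Poisson noise. A clean (noise-free) stack and the per-frame
aggregate centers are always returned alongside the noisy data so that
denoising and tracking can be evaluated against ground truth.

Aggregate diffusion follows the classic Monte-Carlo scheme: per frame and
axis, a Gaussian step of standard deviation sqrt(2 D dt) (converted to
pixels) is drawn via the Box–Muller transform of two uniform deviates.
Flow subtracts a constant v/pixel_size pixels per frame along -x.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional
import warnings

import numpy as np

from .compartment import CompartmentState, RateConstants, trajectory
from .stack import ImageStack

PRESETS = ("basic", "with_neighbor", "mobile_aggregate", "flow_aggregate")


@dataclass(frozen=True)
class MotionParams:
    """Aggregate motion: diffusion coefficient D (µm²/s) and flow speed v
    (µm per frame, applied along the negative x direction)."""

    D: float = 0.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if self.D < 0 or self.v < 0:
            raise ValueError("motion parameters D and v must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Additive/photon noise model.

    model         : 'none', 'gaussian' or 'poisson'
    sigma         : Gaussian std as a fraction of the initial maximum intensity
    photon_scale  : photon counts per intensity unit for the Poisson model
    """

    model: str = "none"
    sigma: float = 0.02
    photon_scale: float = 100.0

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.model!r}; use none, gaussian or poisson")
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")


@dataclass(frozen=True)
class Aggregate:
    """A circular aggregate at a continuous pixel position."""

    center_x: float
    center_y: float
    radius: float
    mobile: bool = False


@dataclass
class SimScene:
    """Full specification of a synthetic FLIP experiment (record of truth).

    Masks are boolean images; the nucleus lies inside the cell, the bleach
    ROI and all aggregates lie in the cytoplasm (cell minus nucleus).
    """

    image_shape: tuple[int, int]
    pixel_size: float  # µm / pixel
    dt: float  # s / frame
    n_frames: int
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    bleach_roi_mask: np.ndarray
    aggregates: list[Aggregate]
    rates: RateConstants
    init: CompartmentState
    neighbor_cell_mask: Optional[np.ndarray] = None
    neighbor_intensity: float = 150.0
    motion: MotionParams = field(default_factory=MotionParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        for name in ("cell_mask", "nucleus_mask", "bleach_roi_mask"):
            m = getattr(self, name)
            if m.shape != (h, w) or m.dtype != bool:
                raise ValueError(f"{name} must be a boolean ({h}, {w}) image")
        if np.any(self.nucleus_mask & ~self.cell_mask):
            raise ValueError("nucleus_mask must lie inside cell_mask")
        cyto = self.cell_mask & ~self.nucleus_mask
        if np.any(self.bleach_roi_mask & ~cyto):
            raise ValueError("bleach_roi_mask must lie in the cytoplasm (cell minus nucleus)")
        if self.neighbor_cell_mask is not None and np.any(self.neighbor_cell_mask & self.cell_mask):
            raise ValueError("neighbor_cell_mask must not overlap the cell")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def brownian_sigma_px(D: float, dt: float, pixel_size: float) -> float:
    """Per-axis Brownian step standard deviation in pixels: sqrt(2 D dt)/pixel_size."""
    if D < 0 or dt < 0:
        raise ValueError("D and dt must be >= 0")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return float(np.sqrt(2.0 * D * dt) / pixel_size)


def box_muller(rng: np.random.Generator, size: int = 2) -> np.ndarray:
    """Standard-normal deviates from pairs of uniforms via the Box–Muller transform."""
    n_pairs = (size + 1) // 2
    u1 = rng.uniform(size=n_pairs)
    u2 = rng.uniform(size=n_pairs)
    r = np.sqrt(-2.0 * np.log1p(-u1))  # log1p(-u) avoids log(0)
    z = np.concatenate([r * np.cos(2 * np.pi * u2), r * np.sin(2 * np.pi * u2)])
    return z[:size]


def simulate_trajectory(
    start_xy: tuple[float, float],
    motion: MotionParams,
    n_frames: int,
    dt: float,
    pixel_size: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-frame (x, y) centers in continuous pixels for a mobile aggregate.

    Frame 0 is the start position; each subsequent frame adds a Box–Muller
    Gaussian step of std sqrt(2 D dt)/pixel_size per axis and shifts
    x by -v/pixel_size (flow is µm per frame).
    """
    sigma = brownian_sigma_px(motion.D, dt, pixel_size)
    flow_px = motion.v / pixel_size
    xy = np.empty((n_frames, 2))
    xy[0] = start_xy
    for n in range(1, n_frames):
        step = sigma * box_muller(rng, 2) if sigma > 0 else np.zeros(2)
        xy[n, 0] = xy[n - 1, 0] + step[0] - flow_px
        xy[n, 1] = xy[n - 1, 1] + step[1]
    return xy


def disk_coverage(shape: tuple[int, int], cx: float, cy: float, radius: float) -> np.ndarray:
    """Anti-aliased disk: per-pixel area coverage in [0, 1].

    The coverage of a pixel (unit square centered on the grid point) is
    approximated from the signed distance of the pixel center to the
    circle edge, which is exact for straight edges and accurate to ~1% of
    a pixel for the radii used here. Avoids the intensity flicker that
    hard (binary) rasterization produces for moving sub-pixel centers.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - cx, yy - cy)
    return np.clip(radius - dist + 0.5, 0.0, 1.0)


def _ellipse_mask(shape: tuple[int, int], cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0


def _disk_mask(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return np.hypot(xx - cx, yy - cy) <= r


def default_scene(preset: str = "basic", *, n_frames: int = 300, dt: float = 1.0,
                  noise: Optional[NoiseParams] = None, seed: int = 0) -> SimScene:
    """A fully specified 128×128 test scene.

    All presets share the same geometry: an elliptical cell with an
    elliptical nucleus, three circular aggregates of radii 2, 4 and 6 px
    in the cytoplasm, and a circular bleach ROI of radius 5 px. Kinetic
    rates are the validation set whose analytic eigenvalues are
    {-0.005, -0.6342, -0.01577} s^-1.

    Presets
    -------
    basic            : static scene, no neighbor
    with_neighbor    : adds an unbleached neighboring cell (constant intensity)
    mobile_aggregate : smallest aggregate diffuses with D = 0.004 µm²/s
    flow_aggregate   : smallest aggregate drifts at v = 0.00625 µm/frame (-x)
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available presets: {', '.join(PRESETS)}")

    shape = (128, 128)
    cell = _ellipse_mask(shape, cx=58.0, cy=64.0, rx=48.0, ry=56.0)
    nucleus = _ellipse_mask(shape, cx=44.0, cy=52.0, rx=17.0, ry=13.0)
    bleach = _disk_mask(shape, cx=62.0, cy=100.0, r=5.0)
    aggregates = [
        Aggregate(center_x=78.0, center_y=48.0, radius=2.0, mobile=False),
        Aggregate(center_x=86.0, center_y=72.0, radius=4.0, mobile=False),
        Aggregate(center_x=52.0, center_y=92.0, radius=6.0, mobile=False),
    ]

    neighbor = None
    motion = MotionParams(D=0.0, v=0.0)
    if preset == "with_neighbor":
        neighbor = _ellipse_mask(shape, cx=117.0, cy=20.0, rx=14.0, ry=17.0)
        neighbor &= ~cell
    elif preset == "mobile_aggregate":
        aggregates[0] = Aggregate(78.0, 48.0, 2.0, mobile=True)
        motion = MotionParams(D=0.004, v=0.0)
    elif preset == "flow_aggregate":
        aggregates[0] = Aggregate(78.0, 48.0, 2.0, mobile=True)
        motion = MotionParams(D=0.0, v=0.00625)

    return SimScene(
        image_shape=shape,
        pixel_size=0.125,
        dt=dt,
        n_frames=n_frames,
        cell_mask=cell,
        nucleus_mask=nucleus,
        bleach_roi_mask=bleach,
        aggregates=aggregates,
        rates=RateConstants(k1=0.016194, k_m1=0.016194, k2=0.005, k3=0.617582),
        init=CompartmentState(A=200.0, C=100.0, N=100.0),
        neighbor_cell_mask=neighbor,
        motion=motion,
        noise=noise if noise is not None else NoiseParams(model="none"),
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Noise-free stack and per-frame aggregate centers emitted with every render."""

    clean: ImageStack
    aggregate_centers: np.ndarray  # (n_aggregates, n_frames, 2) as (x, y)


def render_stack(scene: SimScene) -> tuple[ImageStack, GroundTruth]:
    """Render the scene into a (noisy stack, ground truth) pair.

    Pixel values per frame n at t = n*dt: N(t) in the nucleus, C(t) in the
    cytoplasm (the bleach ROI is part of the cytoplasmic pool), A(t) on
    aggregate disks, a constant on the neighbor cell, 0 in background.
    Mobile aggregates are re-rasterized each frame at their continuous
    centers with anti-aliased edges. The same scene (including seed)
    always yields a bit-identical stack.
    """
    scene.validate()
    h, w = scene.image_shape
    times = np.arange(scene.n_frames) * scene.dt
    traj = trajectory(scene.rates, scene.init, times)  # (n_frames, 3): A, C, N
    A_t, C_t, N_t = traj[:, 0], traj[:, 1], traj[:, 2]

    rng = np.random.default_rng(scene.seed)
    cyto = scene.cell_mask & ~scene.nucleus_mask

    # motion trajectories (drawn first so noise draws do not perturb them)
    centers = np.empty((len(scene.aggregates), scene.n_frames, 2))
    for i, agg in enumerate(scene.aggregates):
        if agg.mobile and (scene.motion.D > 0 or scene.motion.v > 0):
            centers[i] = simulate_trajectory(
                (agg.center_x, agg.center_y), scene.motion,
                scene.n_frames, scene.dt, scene.pixel_size, rng,
            )
        else:
            centers[i, :, 0] = agg.center_x
            centers[i, :, 1] = agg.center_y

    # clip trajectories that would carry an aggregate outside the cell
    for i, agg in enumerate(scene.aggregates):
        xs, ys = centers[i, :, 0], centers[i, :, 1]
        out = (xs - agg.radius < 0) | (xs + agg.radius > w - 1) | \
              (ys - agg.radius < 0) | (ys + agg.radius > h - 1)
        if np.any(out):
            warnings.warn(f"aggregate {i} trajectory clipped at the image boundary")
            centers[i, :, 0] = np.clip(xs, agg.radius, w - 1 - agg.radius)
            centers[i, :, 1] = np.clip(ys, agg.radius, h - 1 - agg.radius)

    static_covers = [
        disk_coverage((h, w), agg.center_x, agg.center_y, agg.radius)
        for agg in scene.aggregates
    ]

    clean = np.zeros((scene.n_frames, h, w))
    for n in range(scene.n_frames):
        frame = np.zeros((h, w))
        frame[cyto] = C_t[n]
        frame[scene.nucleus_mask] = N_t[n]
        if scene.neighbor_cell_mask is not None:
            frame[scene.neighbor_cell_mask] = scene.neighbor_intensity
        for i, agg in enumerate(scene.aggregates):
            moved = not np.allclose(centers[i, n], (agg.center_x, agg.center_y))
            cov = (
                disk_coverage((h, w), centers[i, n, 0], centers[i, n, 1], agg.radius)
                if moved else static_covers[i]
            )
            # blend aggregate intensity over the underlying compartment
            frame = frame * (1.0 - cov) + cov * A_t[n]
        clean[n] = frame

    noisy = clean.copy()
    if scene.noise.model == "gaussian" and scene.noise.sigma > 0:
        sigma_abs = scene.noise.sigma * clean[0].max()
        noisy = clean + rng.normal(scale=sigma_abs, size=clean.shape)
    elif scene.noise.model == "poisson":
        counts = rng.poisson(np.maximum(clean, 0.0) * scene.noise.photon_scale)
        noisy = counts / scene.noise.photon_scale

    gt = GroundTruth(clean=ImageStack(clean, scene.dt), aggregate_centers=centers)
    return ImageStack(noisy, scene.dt), gt


def scene_to_json(scene: SimScene) -> str:
    """Serialize a scene to JSON (masks as run-length-free index lists are
    too heavy; masks are stored as packed bit strings per row)."""
    d = {
        "image_shape": list(scene.image_shape),
        "pixel_size": scene.pixel_size,
        "dt": scene.dt,
        "n_frames": scene.n_frames,
        "aggregates": [asdict(a) for a in scene.aggregates],
        "rates": asdict(scene.rates),
        "init": asdict(scene.init),
        "neighbor_intensity": scene.neighbor_intensity,
        "motion": asdict(scene.motion),
        "noise": asdict(scene.noise),
        "seed": scene.seed,
        "masks": {
            name: np.packbits(getattr(scene, name)).tobytes().hex()
            if getattr(scene, name) is not None else None
            for name in ("cell_mask", "nucleus_mask", "bleach_roi_mask", "neighbor_cell_mask")
        },
    }
    return json.dumps(d, indent=1)


def scene_from_json(text: str) -> SimScene:
    d = json.loads(text)
    shape = tuple(d["image_shape"])
    n_px = shape[0] * shape[1]

    def unpack(hexstr):
        if hexstr is None:
            return None
        bits = np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))
        return bits[:n_px].reshape(shape).astype(bool)

    return SimScene(
        image_shape=shape,
        pixel_size=d["pixel_size"],
        dt=d["dt"],
        n_frames=d["n_frames"],
        cell_mask=unpack(d["masks"]["cell_mask"]),
        nucleus_mask=unpack(d["masks"]["nucleus_mask"]),
        bleach_roi_mask=unpack(d["masks"]["bleach_roi_mask"]),
        aggregates=[Aggregate(**a) for a in d["aggregates"]],
        rates=RateConstants(**d["rates"]),
        init=CompartmentState(**d["init"]),
        neighbor_cell_mask=unpack(d["masks"]["neighbor_cell_mask"]),
        neighbor_intensity=d["neighbor_intensity"],
        motion=MotionParams(**d["motion"]),
        noise=NoiseParams(**d["noise"]),
        seed=d["seed"],
    )
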