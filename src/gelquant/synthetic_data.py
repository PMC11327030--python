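"""Synthetic inputs with known ground truth for every pipeline stage.

Real 3D-collagen microscopy is replaced by generators whose statistical
signatures are controlled analytically:

* cell trajectories — Brownian, fractional Brownian (tunable anomalous
  exponent α = 2H), and persistent random walks (tunable directionality);
* 2D fiber-field images emulating second-harmonic-generation (SHG)
  pictures of collagen gels, with tunable fiber count, length, width and
  orientation concentration — denser gels are emulated by more, shorter,
  less aligned fibers;
* invasion-depth samples over a ~1,000 μm gel;
* two-channel 3D ellipsoidal cell phantoms (membrane shell + nuclear
  core) with closed-form volume and axis lengths.

All generators draw from a single seeded :class:`numpy.random.Generator`
per call, so identical seed and parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import linalg

from .trajectory_metrics import Trajectory

__all__ = [
    "SimConfig",
    "FiberFieldSpec",
    "PhantomTruth",
    "FiberSegment",
    "simulate_brownian_track",
    "simulate_fbm_track",
    "simulate_persistent_track",
    "generate_fiber_image",
    "generate_cell_phantom",
    "sample_invasion_depths",
    "truncated_exponential_mean",
    "truncated_exponential_median",
    "fiber_density_presets",
]


@dataclass
class SimConfig:
    """Shared acquisition geometry for the simulators.

    Defaults mirror a 24 h live-imaging run at one frame per 10 min
    (144 frames) — the sampling used for the migration statistics.
    """

    n_steps: int = 144
    frame_interval: float = 10.0  # minutes
    seed: int = 0
    pixel_size: float = 0.5  # μm/pixel, 2D images
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # μm, (z, y, x)

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FiberFieldSpec:
    """Parameters of a rendered fiber field.

    ``orientation_kappa`` is the concentration of a von Mises
    distribution over fiber angles: 0 gives an isotropic field, large
    values a strongly aligned one.  Lengths and width are in μm and are
    converted with the :class:`SimConfig` pixel size at render time.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_fibers: int = 100
    mean_length: float = 20.0  # μm
    length_sd: float = 5.0  # μm
    width: float = 1.0  # μm
    orientation_kappa: float = 0.0
    orientation_mean_deg: float = 0.0
    background_level: float = 8.0
    fiber_level: float = 120.0
    noise_sd: float = 4.0
    saturation: float = 255.0

    def __post_init__(self) -> None:
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be non-negative")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.orientation_kappa < 0:
            raise ValueError("orientation_kappa must be non-negative")
        if min(self.image_shape) < 16:
            raise ValueError("image_shape must be at least 16×16")


@dataclass
class PhantomTruth:
    """Ground truth of an ellipsoidal cell phantom.

    Semi-axes are ordered a ≥ b ≥ c (μm); the longitudinal axis of the
    phantom is 2a and its volume 4/3·π·a·b·c.
    """

    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float]  # μm, (z, y, x)
    rotation_deg_z: float = 0.0  # in-plane rotation of the long axis

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not a >= b >= c > 0:
            raise ValueError("semi-axes must satisfy a ≥ b ≥ c > 0")

    @property
    def true_volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    @property
    def true_longitudinal(self) -> float:
        return 2.0 * self.semi_axes[0]

    @property
    def true_transverse(self) -> float:
        return 2.0 * self.semi_axes[1]


@dataclass
class FiberSegment:
    """Rendered ground-truth line segment (μm coordinates, row/col order)."""

    start: tuple[float, float]
    end: tuple[float, float]
    length: float  # μm
    angle_rad: float


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def simulate_brownian_track(
    config: SimConfig,
    step_sigma: float,
    ndim: int = 2,
    track_id: str = "brownian",
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Pure random walk: i.i.d. zero-mean Gaussian increments per axis.

    ``step_sigma`` is the per-axis standard deviation of one frame's
    displacement (μm).  The ensemble MSD is the random-walk closed form
    MSD(τ) = ndim · σ² · τ (τ in frames), hence a fitted α of 1 — the
    Brownian reference the α estimator must recover.
    """
    if step_sigma < 0:
        raise ValueError("step_sigma must be non-negative")
    rng = config.rng() if rng is None else rng
    steps = rng.normal(0.0, step_sigma, size=(config.n_steps - 1, ndim))
    positions = np.vstack([np.zeros(ndim), np.cumsum(steps, axis=0)])
    return Trajectory(track_id, config.frame_interval, positions)


@lru_cache(maxsize=16)
def _fbm_cholesky(n: int, hurst: float) -> np.ndarray:
    """Lower Cholesky factor of the fBm covariance at integer times 1..n.

    cov(B_H(s), B_H(t)) = ½ (s^2H + t^2H − |t−s|^2H).  Exact by
    construction — no spectral truncation — and cheap at track lengths
    of a few hundred frames.
    """
    t = np.arange(1, n + 1, dtype=float)
    h2 = 2.0 * hurst
    cov = 0.5 * (t[:, None] ** h2 + t[None, :] ** h2 - np.abs(t[:, None] - t[None, :]) ** h2)
    return linalg.cholesky(cov, lower=True)


def simulate_fbm_track(
    config: SimConfig,
    hurst: float,
    scale: float = 1.0,
    ndim: int = 2,
    track_id: str = "fbm",
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Fractional Brownian motion with Hurst exponent H per coordinate.

    The ensemble MSD grows as τ^(2H); a cohort of such tracks therefore
    has a known anomalous exponent α = 2H, covering the subdiffusive
    regime (H < ½) seen for cells confined in dense collagen.  ``scale``
    sets the per-frame displacement scale in μm.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie strictly inside (0, 1)")
    rng = config.rng() if rng is None else rng
    chol = _fbm_cholesky(config.n_steps - 1, hurst)
    z = rng.standard_normal(size=(config.n_steps - 1, ndim))
    path = scale * (chol @ z)
    positions = np.vstack([np.zeros(ndim), path])
    return Trajectory(track_id, config.frame_interval, positions)


def simulate_persistent_track(
    config: SimConfig,
    speed: float,
    angular_kappa: float,
    track_id: str = "persistent",
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """2D persistent random walk with von Mises turning angles.

    Step length is constant (speed × frame interval); the heading turns
    by a von Mises(0, κ) angle each frame.  κ = 0 reproduces an
    uncorrelated random walk of fixed step length; κ → ∞ approaches
    ballistic motion with persistence → 1.
    """
    if speed < 0:
        raise ValueError("speed must be non-negative")
    if angular_kappa < 0:
        raise ValueError("angular_kappa must be non-negative")
    rng = config.rng() if rng is None else rng
    n_steps = config.n_steps - 1
    step = speed * config.frame_interval
    heading0 = rng.uniform(-np.pi, np.pi)
    if angular_kappa > 1e8:  # ballistic limit; vonmises sampling degenerates
        turns = np.zeros(n_steps - 1)
    else:
        turns = rng.vonmises(0.0, angular_kappa, size=n_steps - 1)
    headings = heading0 + np.concatenate([[0.0], np.cumsum(turns)])
    steps = step * np.column_stack([np.cos(headings), np.sin(headings)])
    positions = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return Trajectory(track_id, config.frame_interval, positions)


# ---------------------------------------------------------------------------
# Fiber fields
# ---------------------------------------------------------------------------


def generate_fiber_image(
    spec: FiberFieldSpec,
    config: SimConfig,
) -> tuple["FiberImage", list[FiberSegment]]:
    """Render an SHG-like fiber field with known segment ground truth.

    Fibers are anti-aliased straight segments with centers uniform over
    the field, Gaussian lengths truncated at > 0, von Mises angles and
    the given width; intensities add where fibers overlap and clip at
    saturation, emulating SHG signal accumulation.  Gaussian read noise
    is added last.  Returns the image and the rendered segment list.
    """
    from .collagen_structure import FiberImage  # local import avoids a cycle

    rng = config.rng()
    h, w = spec.image_shape
    px = config.pixel_size
    img = np.full((h, w), float(spec.background_level))
    half_w_px = 0.5 * spec.width / px

    segments: list[FiberSegment] = []
    for _ in range(spec.n_fibers):
        length = -1.0
        while length <= 0:
            length = rng.normal(spec.mean_length, spec.length_sd)
        angle = rng.vonmises(np.deg2rad(spec.orientation_mean_deg),
                             spec.orientation_kappa) if spec.orientation_kappa > 0 \
            else rng.uniform(-np.pi, np.pi)
        cy, cx = rng.uniform(0, h) , rng.uniform(0, w)
        half_px = 0.5 * length / px
        dy, dx = np.sin(angle) * half_px, np.cos(angle) * half_px
        p0 = np.array([cy - dy, cx - dx])
        p1 = np.array([cy + dy, cx + dx])
        _render_segment(img, p0, p1, half_w_px, spec.fiber_level)
        segments.append(
            FiberSegment(
                start=(p0[0] * px, p0[1] * px),
                end=(p1[0] * px, p1[1] * px),
                length=length,
                angle_rad=float(angle),
            )
        )
    np.clip(img, 0.0, spec.saturation, out=img)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        np.clip(img, 0.0, spec.saturation, out=img)
    return FiberImage(data=img, pixel_size=px), segments


def _render_segment(
    img: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    half_width_px: float,
    level: float,
) -> None:
    """Additively draw one capsule (segment + round caps), anti-aliased.

    Coverage falls linearly from 1 to 0 across the last pixel of the
    capsule boundary (distance-based anti-aliasing).
    """
    h, w = img.shape
    pad = half_width_px + 1.5
    r0 = max(int(np.floor(min(p0[0], p1[0]) - pad)), 0)
    r1 = min(int(np.ceil(max(p0[0], p1[0]) + pad)) + 1, h)
    c0 = max(int(np.floor(min(p0[1], p1[1]) - pad)), 0)
    c1 = min(int(np.ceil(max(p0[1], p1[1]) + pad)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    pts = np.stack([rows, cols], axis=-1).astype(float)
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0.0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / len2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    coverage = np.clip(half_width_px + 0.5 - dist, 0.0, 1.0)
    img[r0:r1, c0:c1] += level * coverage


def fiber_density_presets(
    image_shape: tuple[int, int] = (256, 256),
) -> dict[str, FiberFieldSpec]:
    """Fiber-field specs emulating 1 / 3 / 6 mg/mL collagen gels.

    Encodes the qualitative structure of increasingly dense gels: more
    fibers that are shorter, thinner and less aligned, giving smaller
    free spaces and pores.  Mean fiber lengths follow the 33 / 16 / 8 μm
    ordering reported for such gels; the remaining values are chosen
    once as plausible render settings, not fitted to any measurement.
    """
    return {
        "1 mg/mL": FiberFieldSpec(
            image_shape=image_shape, n_fibers=40, mean_length=33.0,
            length_sd=6.0, width=1.2, orientation_kappa=3.0),
        "3 mg/mL": FiberFieldSpec(
            image_shape=image_shape, n_fibers=150, mean_length=16.0,
            length_sd=4.0, width=1.0, orientation_kappa=1.0),
        "6 mg/mL": FiberFieldSpec(
            image_shape=image_shape, n_fibers=500, mean_length=8.0,
            length_sd=2.0, width=0.8, orientation_kappa=0.2),
    }


# ---------------------------------------------------------------------------
# 3D cell phantoms
# ---------------------------------------------------------------------------


def generate_cell_phantom(
    truth: PhantomTruth,
    config: SimConfig,
    noise_sd: float = 0.0,
    shape: tuple[int, int, int] = (64, 64, 64),
    membrane_level: float = 200.0,
    nucleus_level: float = 180.0,
    background_level: float = 10.0,
    shell_inner_fraction: float = 0.6,
    nucleus_fraction: float = 0.55,
) -> tuple[np.ndarray, PhantomTruth]:
    """Two-channel 3D phantom: membrane-analog shell + nucleus-analog core.

    Channel 0 is a bright ellipsoidal shell (normalized ellipsoid radius
    in [``shell_inner_fraction``, 1]), channel 1 a bright concentric
    inner ellipsoid (radius ≤ ``nucleus_fraction``); both sit on a dark
    background with optional Gaussian noise.  The long axis a lies along
    x, optionally rotated by ``truth.rotation_deg_z`` in the x–y plane.
    Returns a ``(2, z, y, x)`` float array and the truth record.

    The phantom must fit inside the volume with a ≥ 2-voxel margin on
    every axis; violating that raises ``ValueError``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    a, b, c = truth.semi_axes
    vz, vy, vx = config.voxel_size
    cz, cy, cx = truth.center
    # conservative bound on spatial extent: rotation in x-y mixes a and b
    ext_xy = max(a, b)
    extents = (c, ext_xy, ext_xy)  # (z, y, x) half-extents, μm
    dims_um = (shape[0] * vz, shape[1] * vy, shape[2] * vx)
    voxels = (vz, vy, vx)
    for cen, ext, dim, v in zip((cz, cy, cx), extents, dims_um, voxels):
        if cen - ext < 2 * v or cen + ext > dim - 2 * v:
            raise ValueError("phantom does not fit with a 2-voxel margin")

    zs = (np.arange(shape[0]) + 0.5) * vz - cz
    ys = (np.arange(shape[1]) + 0.5) * vy - cy
    xs = (np.arange(shape[2]) + 0.5) * vx - cx
    zg, yg, xg = np.meshgrid(zs, ys, xs, indexing="ij")
    theta = np.deg2rad(truth.rotation_deg_z)
    # rotate lab coordinates into the ellipsoid frame (long axis along x)
    xr = np.cos(theta) * xg + np.sin(theta) * yg
    yr = -np.sin(theta) * xg + np.cos(theta) * yg
    rho = np.sqrt((xr / a) ** 2 + (yr / b) ** 2 + (zg / c) ** 2)

    membrane = np.full(shape, background_level)
    membrane[(rho >= shell_inner_fraction) & (rho <= 1.0)] = membrane_level
    nucleus = np.full(shape, background_level)
    nucleus[rho <= nucleus_fraction] = nucleus_level
    stack = np.stack([membrane, nucleus])
    if noise_sd > 0:
        rng = config.rng()
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    return stack, truth


# ---------------------------------------------------------------------------
# Invasion depths
# ---------------------------------------------------------------------------


def sample_invasion_depths(
    n_cells: int,
    mean_depth: float,
    max_depth: float = 1000.0,
    seed: int = 0,
) -> np.ndarray:
    """Exponential invasion depths truncated to [0, ``max_depth``].

    Truncation is by rejection (redraw values beyond the gel), not
    clamping, so the sample follows the analytic truncated-exponential
    density and its closed-form mean/median remain valid checks.  The
    exponential is a stand-in: the true depth distribution of invading
    cells is not characterized, only its density-dependent skew.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if mean_depth <= 0 or max_depth <= 0:
        raise ValueError("mean_depth and max_depth must be positive")
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while len(out) < n_cells:
        draw = rng.exponential(mean_depth, size=max(n_cells, 256))
        out = np.concatenate([out, draw[draw <= max_depth]])
    return out[:n_cells]


def truncated_exponential_mean(mean_depth: float, max_depth: float) -> float:
    """Mean of an exponential(μ) truncated to [0, T]: μ − T·e^(−T/μ)/(1−e^(−T/μ))."""
    r = max_depth / mean_depth
    return mean_depth - max_depth * np.exp(-r) / (1.0 - np.exp(-r))


def truncated_exponential_median(mean_depth: float, max_depth: float) -> float:
    """Median of an exponential(μ) truncated to [0, T] (invert the CDF at ½)."""
    p_t = 1.0 - np.exp(-max_depth / mean_depth)
    return -mean_depth * np.log(1.0 - 0.5 * p_t)
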