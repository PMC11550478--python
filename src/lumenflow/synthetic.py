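"""Synthetic two-channel time-lapse scenes with known ground truth.

Scenes emulate the imaging situation the pipeline quantifies: a bright
peripheral junctional ring of punctate fluorophore clusters around a dimmer
apical compartment, advected by configurable flow fields (uniform drift,
outward ring expansion, scheduled inward bursts in angular sub-regions,
rigid rotation), imaged with a Gaussian point-spread proxy, Poisson photon
noise and Gaussian read noise at a default frame interval of 36 s.

Particles live at sub-pixel floating-point positions; rendering integrates
the Gaussian kernel over each pixel (erf-based), so sub-pixel displacements
are faithfully encoded for PIV sub-pixel recovery tests.  A photoconversion
event switches the intensity of particles inside a chosen region from the
green to the magenta channel, after which turnover re-equilibrates the
labels at a configurable exchange rate.

Every scene is deterministic given its seed and returns a
:class:`SceneTruth` (trajectories, label history, analytic flow, true masks)
so each quantification stage can be verified by parameter recovery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.special import erf

from .segmentation import (
    BinaryMask,
    CompartmentPartition,
    RoiPolygon,
    partition_compartment,
    rasterize,
)
from .stack_io import ImageStack

SQRT2 = math.sqrt(2.0)

FLOW_MODES = (
    "static",
    "translation",
    "outward",
    "inward",
    "lateral_expansion",
    "inward_burst",
    "rotation",
    "mixed",
)


@dataclass(frozen=True)
class ConversionParams:
    """A photoconversion event: when, where, and how fast labels exchange."""

    t_convert_s: float
    roi: RoiPolygon
    exchange_rate_per_s: float = 0.0
    stochastic: bool = False


@dataclass
class SceneParams:
    """Full description of a synthetic scene; defaults mirror a wild-type
    junctional ring imaged at 36-s intervals with 0.1 µm pixels."""

    image_shape: tuple[int, int] = (160, 160)
    pixel_size_um: float = 0.1
    frame_interval_s: float = 36.0
    n_frames: int = 11
    ring_center_px: tuple[float, float] = (79.5, 79.5)
    ring_radius_um: float = 4.0  # outer ROI radius
    band_thickness_um: float = 0.8
    n_particles: int = 140
    intensity_per_channel: tuple[float, float] = (2.0e5, 2.0e5)
    psf_sigma_um: float = 0.1
    intensity_spread: float = 0.5  # per-particle brightness heterogeneity, 0..<1
    flow_mode: str = "static"
    flow_params: dict = field(default_factory=dict)
    channel_allocation: tuple[float, float] = (0.85, 0.15)
    conversion: ConversionParams | None = None
    noise_poisson_gain: float = 1.0  # variance = gain x mean; 0 disables
    noise_gaussian_sd: float = 2.0
    placement: str = "ring_compartments"  # or "uniform"
    placement_margin_um: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        ny, nx = self.image_shape
        if ny < 16 or nx < 16:
            raise ValueError("image_shape too small")
        for name in ("pixel_size_um", "frame_interval_s", "ring_radius_um",
                     "band_thickness_um", "psf_sigma_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_frames < 1 or self.n_particles < 1:
            raise ValueError("n_frames and n_particles must be >= 1")
        if self.flow_mode not in FLOW_MODES:
            raise ValueError(f"unknown flow_mode {self.flow_mode!r}")
        if self.placement not in ("ring_compartments", "uniform"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if not all(0.0 <= f <= 1.0 for f in self.channel_allocation):
            raise ValueError("channel_allocation fractions must lie in [0, 1]")
        if self.band_thickness_um >= self.ring_radius_um:
            raise ValueError("band thicker than ring radius")
        if self.psf_sigma_um / self.pixel_size_um > min(ny, nx) / 4:
            raise ValueError("particle kernel wider than image")
        if self.noise_poisson_gain < 0 or self.noise_gaussian_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        for episode in self.flow_params.get("bursts", []):
            s, e = episode["frames"]
            if not (0 <= s < e <= self.n_frames):
                raise ValueError("burst schedule must lie within [0, n_frames)")
            if not episode.get("sectors"):
                raise ValueError("burst episode needs at least one angular sector")
        if self.conversion is not None:
            c = self.conversion
            if not 0 <= c.t_convert_s <= (self.n_frames - 1) * self.frame_interval_s:
                raise ValueError("conversion time outside the scene")
            if c.exchange_rate_per_s < 0:
                raise ValueError("exchange rate must be >= 0")

    @property
    def ring_radius_px(self) -> float:
        return self.ring_radius_um / self.pixel_size_um

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_um / self.pixel_size_um

    def ring_roi(self, n_vertices: int = 64) -> RoiPolygon:
        """The circular measurement ROI enclosing ring plus apical interior."""
        cx, cy = self.ring_center_px
        theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        verts = np.stack(
            [cx + self.ring_radius_px * np.cos(theta),
             cy + self.ring_radius_px * np.sin(theta)], axis=1
        )
        return RoiPolygon(verts, label="ring")


@dataclass
class SceneTruth:
    """Ground truth of a generated scene."""

    times_s: np.ndarray  # (T,)
    trajectories: np.ndarray  # (T, N, 2) particle (x, y) px, before rendering
    amplitudes: np.ndarray  # (T, N, 2) per-particle per-channel intensity
    converted: np.ndarray | None  # (N,) bool, None if no conversion
    masks: dict[str, BinaryMask]
    roi: RoiPolygon
    params: SceneParams
    flow: Callable[[np.ndarray, float], np.ndarray]  # (N,2) px, t_s -> µm/s

    @property
    def n_particles(self) -> int:
        return self.trajectories.shape[1]


def flow_velocity(params: SceneParams, points_px: np.ndarray, t_s: float) -> np.ndarray:
    """Analytic flow field in µm/s evaluated at pixel positions.

    Radial direction is Euclidean about the ring center; positive speeds
    point outward.  Burst schedules are expressed in frame-pair indices
    (the step from frame k to k+1 is pair k).
    """
    pts = np.atleast_2d(np.asarray(points_px, dtype=float))
    fp = params.flow_params
    mode = params.flow_mode
    vel = np.zeros_like(pts)
    if mode == "static":
        return vel
    if mode == "translation":
        vx, vy = fp["velocity_um_s"]
        vel[:] = (vx, vy)
        return vel

    cx, cy = params.ring_center_px
    dx = (pts[:, 0] - cx) * params.pixel_size_um
    dy = (pts[:, 1] - cy) * params.pixel_size_um
    r = np.hypot(dx, dy)
    safe = r > 1e-9
    rhat = np.zeros_like(pts)
    rhat[safe, 0] = dx[safe] / r[safe]
    rhat[safe, 1] = dy[safe] / r[safe]

    if mode in ("outward", "inward"):
        s = fp.get("speed_um_s", 0.005)
        sign = 1.0 if mode == "outward" else -1.0
        return sign * s * rhat
    if mode == "lateral_expansion":
        s = fp.get("speed_um_s", 0.004)
        inner = params.ring_radius_um - params.band_thickness_um
        in_band = r >= inner
        vel[in_band] = s * rhat[in_band]
        return vel
    if mode == "rotation":
        omega = fp.get("omega_rad_s", 0.1 / 36.0)
        vel[:, 0] = -omega * dy
        vel[:, 1] = omega * dx
        return vel
    if mode == "mixed":
        s = fp.get("speed_um_s", 0.003)
        omega = fp.get("omega_rad_s", 0.05 / 36.0)
        vel[:, 0] = s * rhat[:, 0] - omega * dy
        vel[:, 1] = s * rhat[:, 1] + omega * dx
        return vel
    if mode == "inward_burst":
        # quiet state: ring expansion as in the wild type.  A scheduled
        # episode models a contractile pulse: expansion stalls ring-wide
        # while boundary clusters in the episode's angular sub-regions
        # detach inward; once detached they rest in the apical interior.
        base = fp.get("base_speed_um_s", 0.003)
        burst = fp.get("burst_speed_um_s", 0.015)
        inner = params.ring_radius_um - params.band_thickness_um
        k = int(math.floor(t_s / params.frame_interval_s + 0.5))
        active = [ep for ep in fp.get("bursts", []) if ep["frames"][0] <= k < ep["frames"][1]]
        if not active:
            in_band = r >= inner
            vel[in_band] = base * rhat[in_band]
            return vel
        theta = np.arctan2(dy, dx)
        for episode in active:
            hit = np.zeros(len(pts), dtype=bool)
            for t0, t1 in episode["sectors"]:
                # wrap-aware angular membership
                th = np.mod(theta - t0, 2 * np.pi)
                width = np.mod(t1 - t0, 2 * np.pi)
                hit |= th <= width
            hit &= safe & (r >= inner - 0.3)
            vel[hit] = -burst * rhat[hit]
        return vel
    raise ValueError(f"unknown flow_mode {mode!r}")


def _place_particles(params: SceneParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Initial positions (N,2) px and band-membership flags (N,)."""
    n = params.n_particles
    if params.placement == "uniform":
        ny, nx = params.image_shape
        m = 4 * params.psf_sigma_px + 1
        pos = np.stack(
            [rng.uniform(m, nx - 1 - m, n), rng.uniform(m, ny - 1 - m, n)], axis=1
        )
        return pos, np.zeros(n, dtype=bool)

    cx, cy = params.ring_center_px
    R = params.ring_radius_px
    w = params.band_thickness_um / params.pixel_size_um
    m = params.placement_margin_um / params.pixel_size_um
    n_band = n // 2
    n_int = n - n_band
    r_lo, r_hi = R - w + m, R - m
    if not 0 < r_lo < r_hi:
        raise ValueError("band too thin for the placement margin")
    r_int = R - w - m
    if r_int <= 0:
        raise ValueError("apical interior vanishes under the placement margin")

    def annulus(k, a, b, stratified=False):
        rr = np.sqrt(rng.uniform(a * a, b * b, k))
        if stratified:
            # systematic-random angles: one particle per 2π/k stratum, so the
            # junctional material covers the ring uniformly (as junctions do)
            # and any two half-rings carry equal material to ±1 particle
            th = 2 * np.pi * (np.arange(k) + rng.uniform(0, 1, k)) / k
        else:
            th = rng.uniform(0, 2 * np.pi, k)
        return np.stack([cx + rr * np.cos(th), cy + rr * np.sin(th)], axis=1)

    pos = np.vstack(
        [annulus(n_band, r_lo, r_hi, stratified=True), annulus(n_int, 0.0, r_int)]
    )
    in_band = np.zeros(n, dtype=bool)
    in_band[:n_band] = True
    return pos, in_band


def _base_amplitudes(
    params: SceneParams, in_band: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-particle per-channel intensities realizing the band/interior split.

    Individual clusters vary in brightness (uniform spread ``1 ± s``, as
    junctional puncta do — the heterogeneity also breaks the tangential
    symmetry of an otherwise uniform ring), but the weights are renormalized
    within each compartment group so channel c still places exactly fraction
    ``channel_allocation[c]`` of its total intensity in the band.
    """
    n = len(in_band)
    s = params.intensity_spread
    weights = rng.uniform(1.0 - s, 1.0 + s, n) if s > 0 else np.ones(n)
    n_band_total = int(in_band.sum())
    if s > 0 and params.placement == "ring_compartments" and n_band_total >= 4:
        # antithetic brightness across opposite angular strata: clusters at
        # angle θ and θ+π share a weight, so any half-ring split along a
        # diameter carries the same total material as its partner half
        k = n_band_total
        band_w = weights[:k]
        band_w[k // 2 : 2 * (k // 2)] = band_w[: k // 2]
        weights[:k] = band_w
    amps = np.zeros((n, 2))
    n_band = int(in_band.sum())
    for c in range(2):
        total = params.intensity_per_channel[c]
        f = params.channel_allocation[c]
        if params.placement == "uniform" or n_band == 0 or n_band == n:
            amps[:, c] = total * weights / weights.sum()
            continue
        amps[in_band, c] = f * total * weights[in_band] / weights[in_band].sum()
        amps[~in_band, c] = (1.0 - f) * total * weights[~in_band] / weights[~in_band].sum()
    return amps


def simulate_photoconversion(
    times_s: np.ndarray,
    trajectories: np.ndarray,
    base_amplitudes: np.ndarray,
    roi: RoiPolygon,
    t_convert_s: float,
    exchange_rate_per_s: float,
    image_shape: tuple[int, int],
    stochastic: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-pool label history for a photoconversion pulse-chase.

    At the first frame at or after ``t_convert_s`` every green particle
    inside ``roi`` switches instantly to the magenta channel.  Afterwards
    turnover exchanges converted protein for fresh green protein at rate
    ``exchange_rate_per_s``: by default each converted particle's channel
    weights follow the ensemble expectation (green fraction
    ``1 − exp(−r·(t − t_c))``); with ``stochastic=True`` each particle
    instead flips back at an exponentially distributed time.

    Returns ``(amplitudes (T, N, 2), converted (N,) bool)``.
    """
    T, n = trajectories.shape[:2]
    times_s = np.asarray(times_s, dtype=float)
    k0 = int(np.searchsorted(times_s, t_convert_s - 1e-9))
    if k0 >= T:
        raise ValueError("conversion time is after the last frame")

    mask = rasterize(roi, image_shape).pixels
    ny, nx = image_shape
    px = np.clip(np.round(trajectories[k0]).astype(int), 0, [nx - 1, ny - 1])
    converted = mask[px[:, 1], px[:, 0]] & (base_amplitudes[:, 0] > 0)
    if not converted.any():
        warnings.warn("photoconversion ROI contains no green particles", stacklevel=2)

    amps = np.broadcast_to(base_amplitudes, (T, n, 2)).copy()
    r = exchange_rate_per_s
    if stochastic:
        rng = rng if rng is not None else np.random.default_rng()
        flip_at = np.full(n, np.inf)
        idx = np.nonzero(converted)[0]
        if r > 0:
            flip_at[idx] = t_convert_s + rng.exponential(1.0 / r, idx.size)
    for t in range(k0, T):
        dt = times_s[t] - t_convert_s
        if stochastic:
            magenta_frac = np.where(converted & (times_s[t] < flip_at), 1.0, 0.0)
        else:
            magenta_frac = np.where(converted, math.exp(-r * dt) if r > 0 else 1.0, 0.0)
        green = base_amplitudes[:, 0] * (1.0 - magenta_frac)
        magenta = base_amplitudes[:, 1] + base_amplitudes[:, 0] * magenta_frac
        amps[t, :, 0] = green
        amps[t, :, 1] = magenta
    return amps, converted


def _render_frame(
    shape: tuple[int, int],
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: float,
) -> np.ndarray:
    """Noiseless single-channel frame: pixel-integrated Gaussian kernels."""
    ny, nx = shape
    img = np.zeros((ny, nx))
    reach = max(1, int(math.ceil(4 * sigma_px)))
    denom = SQRT2 * sigma_px
    for (x, y), amp in zip(positions, amplitudes):
        if amp == 0.0:
            continue
        x0 = max(0, int(math.floor(x)) - reach)
        x1 = min(nx - 1, int(math.floor(x)) + reach + 1)
        y0 = max(0, int(math.floor(y)) - reach)
        y1 = min(ny - 1, int(math.floor(y)) + reach + 1)
        if x1 < x0 or y1 < y0:
            continue
        xs = np.arange(x0, x1 + 1)
        ys = np.arange(y0, y1 + 1)
        fx = 0.5 * (erf((xs + 0.5 - x) / denom) - erf((xs - 0.5 - x) / denom))
        fy = 0.5 * (erf((ys + 0.5 - y) / denom) - erf((ys - 0.5 - y) / denom))
        img[y0 : y1 + 1, x0 : x1 + 1] += amp * np.outer(fy, fx)
    return img


def apply_noise(
    clean: np.ndarray,
    poisson_gain: float,
    gaussian_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Camera model: scaled Poisson shot noise (variance = gain × mean) plus
    additive Gaussian read noise, clipped at zero counts."""
    noisy = np.asarray(clean, dtype=float)
    if poisson_gain > 0:
        noisy = poisson_gain * rng.poisson(noisy / poisson_gain).astype(float)
    if gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, gaussian_sd, noisy.shape)
    return np.clip(noisy, 0.0, None)


def generate_scene(params: SceneParams) -> tuple[ImageStack, SceneTruth]:
    """Generate a two-channel scene and its ground truth.

    Deterministic given ``params.seed``: particle placement, trajectories
    (explicit Euler advection by the analytic flow, so each step equals the
    field at the particle position times the frame interval), label history,
    rendering and per-frame noise streams are all derived from it.
    """
    params.validate()
    rng_place = np.random.default_rng([params.seed, 1])
    pos0, in_band = _place_particles(params, rng_place)
    n = params.n_particles
    T = params.n_frames
    dt = params.frame_interval_s
    times = np.arange(T) * dt

    traj = np.empty((T, n, 2))
    traj[0] = pos0
    px_per_um = 1.0 / params.pixel_size_um
    for t in range(T - 1):
        vel = flow_velocity(params, traj[t], times[t])  # µm/s
        traj[t + 1] = traj[t] + vel * dt * px_per_um

    base_amps = _base_amplitudes(params, in_band, rng_place)
    converted = None
    if params.conversion is not None:
        c = params.conversion
        amps, converted = simulate_photoconversion(
            times, traj, base_amps, c.roi, c.t_convert_s, c.exchange_rate_per_s,
            params.image_shape, stochastic=c.stochastic,
            rng=np.random.default_rng([params.seed, 2]),
        )
    else:
        amps = np.broadcast_to(base_amps, (T, n, 2)).copy()

    data = np.empty((T, 2) + tuple(params.image_shape))
    for t in range(T):
        rng_t = np.random.default_rng([params.seed, 100 + t])
        for ch in range(2):
            clean = _render_frame(params.image_shape, traj[t], amps[t, :, ch],
                                  params.psf_sigma_px)
            data[t, ch] = apply_noise(
                clean, params.noise_poisson_gain, params.noise_gaussian_sd, rng_t
            )

    roi = params.ring_roi()
    part = partition_compartment(
        roi, params.image_shape, params.pixel_size_um, params.band_thickness_um
    )
    masks = {
        "ring": rasterize(roi, params.image_shape),
        "band": part.boundary_band,
        "apical": part.apical,
    }
    stack = ImageStack(
        data=data,
        pixel_size_um=params.pixel_size_um,
        frame_interval_s=params.frame_interval_s,
        channel_names=["green", "magenta"],
    )
    truth = SceneTruth(
        times_s=times, trajectories=traj, amplitudes=amps, converted=converted,
        masks=masks, roi=roi, params=params,
        flow=lambda pts, t_s: flow_velocity(params, pts, t_s),
    )
    return stack, truth


def true_velocity_field(
    params: SceneParams,
    t_s: float = 0.0,
    window_px: int = 32,
    overlap_px: int = 16,
):
    """The analytic flow sampled on a PIV interrogation grid.

    Returns a noiseless :class:`~lumenflow.piv.VelocityField` (displacements
    in px per frame interval) — the ground-truth reference against which
    recovered fields and the radial decomposition are checked.
    """
    from .piv import VelocityField

    ny_img, nx_img = params.image_shape
    step = window_px - overlap_px
    half = (window_px - 1) / 2.0
    x0s = np.arange(0, nx_img - window_px + 1, step) + half
    y0s = np.arange(0, ny_img - window_px + 1, step) + half
    gx, gy = np.meshgrid(x0s, y0s)
    pts = np.stack([gx.ravel(), gy.ravel()], axis=1)
    vel = flow_velocity(params, pts, t_s)  # µm/s
    scale = params.frame_interval_s / params.pixel_size_um
    u = (vel[:, 0] * scale).reshape(gx.shape)
    v = (vel[:, 1] * scale).reshape(gx.shape)
    valid = np.ones_like(gx, dtype=bool)
    return VelocityField(
        x=gx, y=gy, u=u, v=v, valid=valid,
        peak_ratio=np.full_like(gx, np.inf),
        window_px=window_px, overlap_px=overlap_px, time_s=t_s,
    )


def halfring_rois(params: SceneParams, gap_px: float = 0.0) -> tuple[RoiPolygon, RoiPolygon]:
    """Upper/lower half rectangles covering the ring — the converted and
    unconverted half-ring measurement regions of a conversion experiment."""
    cx, cy = params.ring_center_px
    R = params.ring_radius_px + 4 * params.psf_sigma_px + 2
    x0, x1 = cx - R, cx + R
    upper = RoiPolygon(
        np.array([[x0, cy - R], [x1, cy - R], [x1, cy - gap_px], [x0, cy - gap_px]]),
        label="converted_half",
    )
    lower = RoiPolygon(
        np.array([[x0, cy + gap_px], [x1, cy + gap_px], [x1, cy + R], [x0, cy + R]]),
        label="unconverted_half",
    )
    return upper, lower


def equal_area_band_width(radius_um: float) -> float:
    """Band width making band and interior areas equal on a disk ROI:
    solving (R − w)² = R²/2 gives w = R·(1 − 1/√2)."""
    return radius_um * (1.0 - 1.0 / SQRT2)


def allocation_params(band_fraction: float, seed: int = 0) -> SceneParams:
    """Scene for boundary-to-apical parameter recovery: fraction
    ``band_fraction`` of the channel-0 intensity in the boundary band, the
    rest in the interior, with equal band/interior areas so the measured B/A
    ratio should recover ``f / (1 − f)``.

    Particles keep a 3σ margin from the band/interior boundary and the ROI
    perimeter so PSF blur does not leak intensity across compartments.
    """
    R = 4.0
    w = equal_area_band_width(R)
    return SceneParams(
        n_frames=1,
        ring_radius_um=R,
        band_thickness_um=w,
        n_particles=500,
        intensity_per_channel=(2.0e5, 2.0e5),
        channel_allocation=(band_fraction, band_fraction),
        psf_sigma_um=0.1,
        placement_margin_um=0.3,
        noise_poisson_gain=1.0,
        noise_gaussian_sd=2.0,
        seed=seed,
    )


def preset(name: str) -> SceneParams:
    """Named scene configurations with documented defaults and fixed seeds."""
    if name == "translation_test":
        # uniform (3, −2) px/frame drift, noiseless
        px, dt = 0.1, 36.0
        return SceneParams(
            n_frames=3,
            n_particles=300,
            flow_mode="translation",
            flow_params={"velocity_um_s": (3.0 * px / dt, -2.0 * px / dt)},
            placement="uniform",
            noise_poisson_gain=0.0,
            noise_gaussian_sd=0.0,
            seed=11,
        )
    if name == "rotation_test":
        # rigid rotation, 0.1 rad per frame, noiseless
        return SceneParams(
            n_frames=3,
            flow_mode="rotation",
            flow_params={"omega_rad_s": 0.1 / 36.0},
            noise_poisson_gain=0.0,
            noise_gaussian_sd=0.0,
            seed=12,
        )
    if name == "wildtype_ring":
        # slow outward band expansion, quiet interior: ten 36-s pairs = 360 s
        return SceneParams(
            n_frames=11,
            flow_mode="lateral_expansion",
            flow_params={"speed_um_s": 0.004},
            channel_allocation=(0.85, 0.15),
            seed=7,
        )
    if name == "rasip1_like":
        # pulsatile inward bursts in two angular sub-regions on a schedule
        # aligned with 2-minute bins (pairs 4-6 and 14-16)
        return SceneParams(
            n_frames=21,
            flow_mode="inward_burst",
            flow_params={
                "base_speed_um_s": 0.003,
                "burst_speed_um_s": 0.015,
                "bursts": [
                    {
                        "frames": (4, 7),
                        "sectors": [
                            (-math.pi / 3, math.pi / 3),
                            (5 * math.pi / 6, 7 * math.pi / 6),
                        ],
                    },
                    {
                        "frames": (14, 17),
                        "sectors": [
                            (math.pi / 3, 2 * math.pi / 3),
                            (4 * math.pi / 3, 5 * math.pi / 3),
                        ],
                    },
                ],
            },
            channel_allocation=(0.85, 0.15),
            seed=8,
        )
    if name == "conversion_test":
        # static ring, green->magenta conversion of the upper half at t=36 s,
        # turnover rate ln(10)/200 so 90% green recovery takes ~200 s
        # a mature ring carries dense, fairly even junctional material, and
        # the half-ring ratio readout presumes comparable halves
        base = SceneParams(
            n_frames=14,
            flow_mode="static",
            n_particles=400,
            intensity_spread=0.3,
            intensity_per_channel=(2.0e5, 0.0),
            channel_allocation=(1.0, 1.0),
            seed=9,
        )
        upper, _ = halfring_rois(base)
        return replace(
            base,
            conversion=ConversionParams(
                t_convert_s=36.0,
                roi=upper,
                exchange_rate_per_s=math.log(10.0) / 200.0,
            ),
        )
    raise ValueError(f"unknown preset {name!r}")


PRESET_NAMES = (
    "wildtype_ring",
    "rasip1_like",
    "translation_test",
    "rotation_test",
    "conversion_test",
)
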