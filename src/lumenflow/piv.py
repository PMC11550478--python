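"""Correlation particle image velocimetry and radial flow decomposition.

Displacement between two consecutive frames is estimated per interrogation
window by normalized, mean-subtracted cross-correlation: the integer
correlation peak gives the displacement to pixel precision, and a three-point
Gaussian (or parabolic) fit through the peak and its neighbours refines it to
sub-pixel precision.  A window is marked invalid — carrying NaN, never a
fabricated vector — when it is (near-)constant, dimmer than an intensity
floor, its peak lies on the search border, or the first-to-second correlation
peak ratio falls below a detectability threshold.

Velocity vectors are decomposed about a compartment center into signed radial
(positive = outward, away from the center) and tangential components, then
aggregated the way ring dynamics are reported: per-window radial displacement
summed over a multi-frame span (heat maps) and mean radial velocity over
fixed time bins (default 2 minutes).
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .stack_io import write_heatmap

__all__ = [
    "VelocityField",
    "RadialVelocityMap",
    "RadialAccumulation",
    "piv_pair",
    "radial_project",
    "heatmap_accumulate",
    "mean_radial_series",
    "arrow_map",
    "render_arrow_map",
]


@dataclass
class VelocityField:
    """Gridded planar displacements (px per frame pair) with validity flags."""

    x: np.ndarray  # (ny, nx) window-center x, px
    y: np.ndarray
    u: np.ndarray  # (ny, nx) displacement x-component, px/pair; NaN if invalid
    v: np.ndarray
    valid: np.ndarray  # (ny, nx) bool
    peak_ratio: np.ndarray
    window_px: int
    overlap_px: int
    time_s: float = 0.0  # acquisition time of the pair's first frame

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.x, self.y, self.u, self.v, self.valid, self.peak_ratio)}
        if len(shapes) != 1:
            raise ValueError("all velocity-field grids must share one shape")
        if np.any(np.isfinite(self.u[~self.valid])) or np.any(np.isfinite(self.v[~self.valid])):
            raise ValueError("invalid windows must carry NaN displacements")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_dataframe(self, frame: int | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x_px": self.x.ravel(),
                "y_px": self.y.ravel(),
                "u_px": self.u.ravel(),
                "v_px": self.v.ravel(),
                "valid": self.valid.ravel(),
                "peak_ratio": self.peak_ratio.ravel(),
            }
        )
        if frame is not None:
            df.insert(0, "frame", frame)
        return df


@dataclass
class RadialVelocityMap:
    """Signed radial/tangential velocities (µm/s) about a compartment center."""

    center: tuple[float, float]
    radial: np.ndarray  # (ny, nx) µm/s, positive outward; NaN if invalid
    tangential: np.ndarray
    valid: np.ndarray
    x: np.ndarray
    y: np.ndarray


@dataclass
class RadialAccumulation:
    """Summed radial displacement over a time span, heat-map ready."""

    total_um: np.ndarray  # per window, invalid pairs contribute 0
    valid_count: np.ndarray  # pairs contributing per window
    mean_um: np.ndarray  # total / count, NaN where count == 0
    x: np.ndarray
    y: np.ndarray
    span_s: float


def _subpixel_offset(cm: float, c0: float, cp: float, mode: str) -> float:
    """Peak-offset refinement from the three correlation samples around the max."""
    if mode == "parabolic":
        den = cm - 2.0 * c0 + cp
        return 0.0 if den == 0 else 0.5 * (cm - cp) / den
    if mode == "gauss3":
        if cm <= 0 or c0 <= 0 or cp <= 0:
            # log fit undefined for non-positive samples: parabolic fallback
            return _subpixel_offset(cm, c0, cp, "parabolic")
        lm, l0, lp = math.log(cm), math.log(c0), math.log(cp)
        den = lm - 2.0 * l0 + lp
        return 0.0 if den == 0 else 0.5 * (lm - lp) / den
    raise ValueError(f"unknown subpixel mode {mode!r} (use 'gauss3', 'parabolic' or 'none')")


def piv_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window_px: int = 32,
    overlap_px: int = 16,
    subpixel: str = "gauss3",
    min_peak_ratio: float = 1.2,
    min_mean_intensity: float = 0.0,
    search_px: int | None = None,
    time_s: float = 0.0,
) -> VelocityField:
    """Cross-correlation PIV between one frame pair.

    Parameters follow common PIV practice: ``window_px`` interrogation
    windows tiled with ``overlap_px`` overlap; displacement searched within
    ``search_px`` (default ``window_px // 2``, the meaningful bound).
    ``subpixel`` is ``"gauss3"``, ``"parabolic"`` or ``"none"`` (integer
    peak only).
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share shape")
    ny_img, nx_img = a.shape
    if window_px < 8:
        raise ValueError("window_px must be >= 8")
    if window_px > min(ny_img, nx_img):
        raise ValueError("interrogation window larger than image")
    if not 0 <= overlap_px < window_px:
        raise ValueError("overlap_px must satisfy 0 <= overlap < window")
    if subpixel not in ("gauss3", "parabolic", "none"):
        raise ValueError(f"unknown subpixel mode {subpixel!r}")
    s = window_px // 2 if search_px is None else int(search_px)
    if not 1 <= s <= window_px - 1:
        raise ValueError("search_px out of range")

    step = window_px - overlap_px
    y0s = np.arange(0, ny_img - window_px + 1, step)
    x0s = np.arange(0, nx_img - window_px + 1, step)
    ny, nx = len(y0s), len(x0s)
    half = (window_px - 1) / 2.0
    gx, gy = np.meshgrid(x0s + half, y0s + half)

    u = np.full((ny, nx), np.nan)
    v = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    ratio = np.full((ny, nx), np.nan)
    mid = window_px - 1  # zero-lag index of the full correlation plane

    for iy, y0 in enumerate(y0s):
        for ix, x0 in enumerate(x0s):
            wa = a[y0 : y0 + window_px, x0 : x0 + window_px]
            wb = b[y0 : y0 + window_px, x0 : x0 + window_px]
            if 0.5 * (wa.mean() + wb.mean()) < min_mean_intensity:
                continue
            wa = wa - wa.mean()
            wb = wb - wb.mean()
            sa, sb = wa.std(), wb.std()
            if sa < 1e-12 or sb < 1e-12:
                continue
            corr = signal.fftconvolve(wb, wa[::-1, ::-1], mode="full")
            region = corr[mid - s : mid + s + 1, mid - s : mid + s + 1]
            py, px = np.unravel_index(np.argmax(region), region.shape)
            n = region.shape[0]
            if py in (0, n - 1) or px in (0, n - 1):
                continue  # peak on search border: displacement not resolvable
            p1 = region[py, px]
            floor = region.min()
            masked = region.copy()
            masked[max(0, py - 1) : py + 2, max(0, px - 1) : px + 2] = floor
            p2 = masked.max()
            pk_ratio = np.inf if p2 <= floor else (p1 - floor) / (p2 - floor)
            ratio[iy, ix] = pk_ratio
            if pk_ratio < min_peak_ratio:
                continue
            du, dv = float(px - s), float(py - s)
            if subpixel != "none":
                du += _subpixel_offset(region[py, px - 1], p1, region[py, px + 1], subpixel)
                dv += _subpixel_offset(region[py - 1, px], p1, region[py + 1, px], subpixel)
            u[iy, ix] = du
            v[iy, ix] = dv
            valid[iy, ix] = True

    return VelocityField(
        x=gx, y=gy, u=u, v=v, valid=valid, peak_ratio=ratio,
        window_px=window_px, overlap_px=overlap_px, time_s=time_s,
    )


def _radial_components_px(
    field: VelocityField, center: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Signed radial/tangential displacement (px/pair) and usable-window mask."""
    cx, cy = center
    if not (np.isfinite(cx) and np.isfinite(cy)):
        raise ValueError("center must be finite")
    dx = field.x - cx
    dy = field.y - cy
    r = np.hypot(dx, dy)
    usable = field.valid & (r > 1e-9)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = (field.u * dx + field.v * dy) / r
        tangential = (-field.u * dy + field.v * dx) / r
    radial[~usable] = np.nan
    tangential[~usable] = np.nan
    return radial, tangential, usable


def radial_project(
    field: VelocityField,
    center: tuple[float, float],
    pixel_size_um: float,
    frame_interval_s: float,
) -> RadialVelocityMap:
    """Decompose a velocity field into radial/tangential µm/s about a center.

    Windows sitting exactly at the center (undefined direction) are treated
    as invalid for radial purposes.
    """
    if field.n_valid == 0:
        raise ValueError("velocity field has no valid windows")
    rad_px, tan_px, usable = _radial_components_px(field, center)
    scale = pixel_size_um / frame_interval_s
    return RadialVelocityMap(
        center=(float(center[0]), float(center[1])),
        radial=rad_px * scale,
        tangential=tan_px * scale,
        valid=usable,
        x=field.x,
        y=field.y,
    )


def _centers_list(centers, n: int) -> list[tuple[float, float]]:
    centers = np.asarray(centers, dtype=float)
    if centers.shape == (2,):
        return [tuple(centers)] * n
    if centers.shape == (n, 2):
        return [tuple(c) for c in centers]
    raise ValueError("centers must be one (x, y) pair or one per field")


def heatmap_accumulate(
    fields: Sequence[VelocityField],
    centers,
    pixel_size_um: float,
) -> RadialAccumulation:
    """Sum per-window radial displacements (µm) over a time-ordered span.

    Windows invalid in a given pair contribute zero to the sum but are
    excluded from the valid count, so both the total displacement and the
    per-pair average are available (the span heat maps can encode either).
    """
    fields = list(fields)
    if not fields:
        raise ValueError("empty field list")
    ref = fields[0]
    ctrs = _centers_list(centers, len(fields))
    total = np.zeros_like(ref.u)
    count = np.zeros(ref.u.shape, dtype=int)
    for f, c in zip(fields, ctrs):
        if f.x.shape != ref.x.shape or not (
            np.allclose(f.x, ref.x) and np.allclose(f.y, ref.y)
        ):
            raise ValueError("all fields must share grid geometry")
        rad_px, _, usable = _radial_components_px(f, c)
        total[usable] += rad_px[usable] * pixel_size_um
        count += usable.astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    span = len(fields) * 1.0
    return RadialAccumulation(
        total_um=total, valid_count=count, mean_um=mean,
        x=ref.x, y=ref.y,
        span_s=float(fields[-1].time_s - fields[0].time_s) if len(fields) > 1 else 0.0,
    )


def mean_radial_series(
    fields: Sequence[VelocityField],
    centers,
    pixel_size_um: float,
    frame_interval_s: float,
    interval_s: float = 120.0,
) -> pd.DataFrame:
    """Mean radial velocity (µm/s) in consecutive non-overlapping time bins.

    Each pair is assigned to the bin containing its first-frame timestamp;
    within a bin the mean runs over every valid window of every pair.  Bins
    with no valid window report NaN.  Default bin width: 120 s.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("empty field list")
    if interval_s < frame_interval_s:
        raise ValueError("interval_s must be at least one frame spacing")
    ctrs = _centers_list(centers, len(fields))
    t0 = min(f.time_s for f in fields)
    tmax = max(f.time_s for f in fields)
    n_bins = int(np.floor((tmax - t0) / interval_s)) + 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    scale = pixel_size_um / frame_interval_s
    for f, c in zip(fields, ctrs):
        rad_px, _, usable = _radial_components_px(f, c)
        k = int((f.time_s - t0) // interval_s)
        sums[k] += np.nansum(rad_px[usable]) * scale
        counts[k] += int(usable.sum())
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start_s": t0 + interval_s * np.arange(n_bins),
            "mean_radial_um_s": means,
            "n_windows": counts,
        }
    )


def arrow_map(
    field: VelocityField,
    center: tuple[float, float],
    pixel_size_um: float,
    frame_interval_s: float,
    display_scale: float = 2.0,
) -> pd.DataFrame:
    """Arrow set for a flow map: drawn length = ``display_scale`` × displacement.

    The underlying data columns (``u_px, v_px, radial_um_s``) are unscaled;
    only the drawn components are magnified (2× by default, the conventional
    visualization exaggeration), and arrow colour encodes the signed radial
    velocity on the diverging scale.
    """
    rmap = radial_project(field, center, pixel_size_um, frame_interval_s)
    keep = rmap.valid.ravel()
    return pd.DataFrame(
        {
            "x_px": field.x.ravel()[keep],
            "y_px": field.y.ravel()[keep],
            "u_px": field.u.ravel()[keep],
            "v_px": field.v.ravel()[keep],
            "draw_dx_px": display_scale * field.u.ravel()[keep],
            "draw_dy_px": display_scale * field.v.ravel()[keep],
            "radial_um_s": rmap.radial.ravel()[keep],
        }
    )


def render_arrow_map(
    arrows: pd.DataFrame,
    path,
    image_shape: tuple[int, int] | None = None,
    background: np.ndarray | None = None,
):
    """Render an arrow map to PNG (quiver coloured by radial velocity)."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if background is not None:
        ax.imshow(background, cmap="gray", origin="upper")
    vmax = float(np.abs(arrows["radial_um_s"]).max()) or 1.0
    q = ax.quiver(
        arrows["x_px"], arrows["y_px"], arrows["draw_dx_px"], arrows["draw_dy_px"],
        arrows["radial_um_s"], cmap="RdBu_r", clim=(-vmax, vmax),
        angles="xy", scale_units="xy", scale=1.0, width=0.005,
    )
    fig.colorbar(q, ax=ax, label="radial velocity (µm/s)")
    if image_shape is not None:
        ax.set_xlim(0, image_shape[1])
        ax.set_ylim(image_shape[0], 0)
    else:
        ax.invert_yaxis()
    ax.set_aspect("equal")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
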