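"""Scalar statistics for junctional segregation, heterogeneity and turnover.

Implements the quantities used to compare wild-type and mutant junctional
phenotypes:

* Dice–Sørensen coefficient between two thresholded masks
  (``2·|A∩B| / (|A|+|B|)``) — colocalization vs segregation of two markers;
* boundary-to-apical (B/A) ratio — mean intensity in the peripheral
  junctional band divided by the mean over the enclosed apical compartment;
* coefficient of variation within a mask — spatial heterogeneity of an
  apical marker;
* whole-cell mean normalization — standardizing a contractility reporter by
  the mean signal over the entire cell;
* line-intensity profiles across junctions;
* photoconversion pulse-chase readouts: half-ring relative-intensity
  recovery curves, time to reach a given fraction, trapezoidal AUC and a
  two-sided unpaired t-test on per-experiment AUCs.

Intensities are used background-uncorrected by default (an optional constant
background can be subtracted where noted); the B/A ratio is invariant to
multiplicative gain but *not* to additive offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .segmentation import BinaryMask, RoiPolygon, rasterize
from .stack_io import ImageStack


@dataclass
class StatRecord:
    """One measured scalar, tidy-table ready."""

    statistic: str
    value: float
    cell_id: str = ""
    condition: str = ""
    timepoint_s: float | None = None

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "value": self.value,
            "cell_id": self.cell_id,
            "condition": self.condition,
            "timepoint_s": self.timepoint_s,
        }


@dataclass
class RecoveryCurve:
    """Relative-intensity time series from a photoconversion experiment."""

    times_s: np.ndarray
    ratio: np.ndarray
    numerator_roi: str = "converted"
    denominator_roi: str = "unconverted"
    channel: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.times_s.shape != self.ratio.shape or self.times_s.ndim != 1:
            raise ValueError("times and ratios must be 1-D series of equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(self.ratio).all():
            raise ValueError("ratios must be finite")


def dice_coefficient(mask_a: BinaryMask, mask_b: BinaryMask) -> float:
    """Dice–Sørensen coefficient ``2|A∩B| / (|A|+|B|)`` in pixel areas.

    1 means full colocalization, 0 complete segregation.  Two empty masks
    have an undefined (0/0) coefficient and raise rather than returning 0.
    """
    a, b = mask_a.pixels, mask_b.pixels
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    area_a = int(a.sum())
    area_b = int(b.sum())
    if area_a + area_b == 0:
        raise ValueError("Dice coefficient undefined: both masks are empty")
    inter = int((a & b).sum())
    return 2.0 * inter / (area_a + area_b)


def _mean_under(image: np.ndarray, mask: np.ndarray, what: str) -> float:
    if not mask.any():
        raise ValueError(f"{what} mask is empty")
    return float(image[mask].mean())


def boundary_apical_ratio(image: np.ndarray, part) -> float:
    """Mean intensity over the boundary band / mean over the apical region."""
    image = np.asarray(image, dtype=float)
    band_mean = _mean_under(image, part.boundary_band.pixels, "boundary band")
    apical_mean = _mean_under(image, part.apical.pixels, "apical")
    if apical_mean <= 0:
        raise ValueError("undefined ratio: apical mean intensity is not positive")
    return band_mean / apical_mean


def coefficient_of_variation(image: np.ndarray, mask: BinaryMask) -> float:
    """Sample standard deviation / mean of intensities under a mask."""
    image = np.asarray(image, dtype=float)
    vals = image[mask.pixels]
    if vals.size < 2:
        raise ValueError("mask must cover at least 2 pixels")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("undefined CV: mean intensity is not positive")
    return float(vals.std(ddof=1) / mean)


def normalize_by_cell_mean(image: np.ndarray, cell_mask: BinaryMask) -> np.ndarray:
    """Divide an image by its mean over the whole-cell mask.

    After normalization the mean over the cell mask is exactly 1, so
    per-region means read directly as fold-change over the cell average.
    """
    image = np.asarray(image, dtype=float)
    mean = _mean_under(image, cell_mask.pixels, "cell")
    if mean <= 0:
        raise ValueError("cell mean intensity must be > 0 to normalize")
    return image / mean


def line_profile(
    image: np.ndarray,
    polyline: np.ndarray,
    width_px: int = 1,
    pixel_size_um: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity profile along a polyline, averaged across a perpendicular width.

    Samples every 1 px of arclength with bilinear interpolation; at each
    sample the intensity is averaged over ``width_px`` (odd) points spread
    perpendicular to the local segment.  Returns ``(arclength_um, intensity)``.
    """
    image = np.asarray(image, dtype=float)
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs >= 2 (x, y) points")
    if width_px < 1 or width_px % 2 == 0:
        raise ValueError("width_px must be a positive odd integer")

    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(seg_len == 0):
        raise ValueError("polyline has zero-length segments")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    s = np.arange(0.0, np.floor(total) + 1.0)

    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    pos = pts[idx] + frac[:, None] * seg[idx]
    tangent = seg[idx] / seg_len[idx, None]
    normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)

    offsets = np.arange(width_px) - (width_px - 1) / 2.0
    sample = pos[None, :, :] + offsets[:, None, None] * normal[None, :, :]
    xs, ys = sample[..., 0], sample[..., 1]
    ny, nx = image.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > nx - 1 or ys.max() > ny - 1:
        raise ValueError("polyline (with width) leaves image bounds")
    vals = ndimage.map_coordinates(image, [ys.ravel(), xs.ravel()], order=1)
    vals = vals.reshape(xs.shape).mean(axis=0)
    return s * pixel_size_um, vals


def halfring_recovery(
    stack: ImageStack,
    converted_roi: RoiPolygon,
    unconverted_roi: RoiPolygon,
    channel: int,
    numerator: str = "converted",
    start_frame: int = 0,
    background: float = 0.0,
) -> RecoveryCurve:
    """Per-frame ratio of mean intensities between the two half-ring ROIs.

    ``numerator="converted"`` gives the green-recovery readout (converted /
    unconverted half); ``numerator="unconverted"`` gives the converted-pool
    spread readout (unconverted / converted half).  Ratios of spatial means
    are used rather than sums so hand-drawn halves of unequal area compare
    fairly.  ``start_frame`` is the first post-conversion frame (conversion
    time is an explicit input, never inferred from the data).
    """
    if numerator not in ("converted", "unconverted"):
        raise ValueError("numerator must be 'converted' or 'unconverted'")
    shape = stack.frame_shape
    conv = rasterize(converted_roi, shape).pixels
    unconv = rasterize(unconverted_roi, shape).pixels
    if not conv.any() or not unconv.any():
        raise ValueError("both half-ring ROIs must be nonempty on this image")
    if stack.n_frames - start_frame < 2:
        raise ValueError("need >= 2 frames after the conversion event")

    num_mask, den_mask = (conv, unconv) if numerator == "converted" else (unconv, conv)
    times, ratios = [], []
    for t in range(start_frame, stack.n_frames):
        img = np.asarray(stack.frame(t, channel), dtype=float) - background
        den = img[den_mask].mean()
        if den <= 0:
            raise ValueError(f"denominator half-ring mean is not positive at frame {t}")
        times.append(stack.times_s[t])
        ratios.append(img[num_mask].mean() / den)
    return RecoveryCurve(
        times_s=np.array(times),
        ratio=np.array(ratios),
        numerator_roi=numerator,
        denominator_roi="unconverted" if numerator == "converted" else "converted",
        channel=stack.channel_names[channel],
    )


def time_to_fraction(curve: RecoveryCurve, fraction: float = 0.9) -> float:
    """First time the ratio reaches ``fraction``, linearly interpolated.

    Measured from the first sample of the curve.  Returns NaN (a
    "not reached" sentinel, not an exception) if the curve never crosses.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    t, r = curve.times_s, curve.ratio
    if r[0] >= fraction:
        return 0.0
    above = np.nonzero(r >= fraction)[0]
    if above.size == 0:
        return float("nan")
    i = int(above[0])
    # linear interpolation between the bracketing samples
    t_cross = t[i - 1] + (fraction - r[i - 1]) * (t[i] - t[i - 1]) / (r[i] - r[i - 1])
    return float(t_cross - t[0])


def auc(curve: RecoveryCurve) -> float:
    """Trapezoidal area under the recovery curve over its time span."""
    if curve.times_s.size < 2:
        raise ValueError("need >= 2 points for an area under the curve")
    return float(np.trapezoid(curve.ratio, curve.times_s))


def compare_groups(
    a, b, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided unpaired two-sample t-test; returns ``(t, p)``.

    The classical pooled (equal-variance) test by default, as used for the
    AUC group comparisons; Welch's correction is available via
    ``equal_var=False``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 samples per group")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
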