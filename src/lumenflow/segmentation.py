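"""Thresholding, mask construction and boundary/apical compartment partition.

The measurement geometry follows the hybrid scheme used for junctional rings:
a user-supplied region of interest (a closed polygon around the junctional
ring) is split into a fixed-width *boundary band* hugging the ROI perimeter
(default 0.5 µm — the junctional compartment) and the remaining *apical*
interior.  Foreground masks come from Otsu's automatic threshold, computed
locally over the analysed region.

Geometry conventions (shared package-wide): 0-based pixel coordinates, pixel
centers at integer coordinates, Y down.  A pixel belongs to a polygon when
its center lies inside; centers falling exactly on an edge are resolved by a
fixed deterministic rule (the test point is nudged by +1e-9 in x and y, so
left/top edges count as inside and right/bottom edges as outside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

import tifffile

#: sub-pixel nudge applied to pixel centers before point-in-polygon tests,
#: making boundary-coincident centers deterministic.
EDGE_EPS = 1e-9


@dataclass(frozen=True)
class RoiPolygon:
    """A simple closed polygon in pixel coordinates labelling a compartment."""

    vertices: np.ndarray  # (N, 2) float, columns (x, y)
    label: str = ""

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        if not np.isfinite(verts).all():
            raise ValueError("polygon vertices must be finite")
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ValueError(f"polygon {self.label!r} is degenerate or self-intersecting")
        if poly.area <= 0:
            raise ValueError(f"polygon {self.label!r} has no enclosed area")
        object.__setattr__(self, "vertices", verts)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_px(self) -> float:
        return self.polygon.area

    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return float(c.x), float(c.y)


@dataclass
class BinaryMask:
    """A boolean Y×X mask plus provenance of the threshold that produced it."""

    pixels: np.ndarray
    source_channel: str = ""
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D (Y, X)")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.pixels & other.pixels)

    def __or__(self, other: "BinaryMask") -> "BinaryMask":
        return BinaryMask(self.pixels | other.pixels)


@dataclass
class CompartmentPartition:
    """Disjoint boundary-band and apical-interior masks tiling a ROI."""

    boundary_band: BinaryMask
    apical: BinaryMask
    roi: RoiPolygon
    band_width_um: float = 0.5

    def __post_init__(self) -> None:
        if (self.boundary_band.pixels & self.apical.pixels).any():
            raise ValueError("boundary band and apical masks must be disjoint")


def read_roi(path: str | Path, label: str | None = None) -> RoiPolygon:
    """Read a whitespace-delimited ``x y`` vertex list (one polygon per file)."""
    path = Path(path)
    verts = np.loadtxt(path, ndmin=2)
    if verts.shape[1] != 2:
        raise ValueError(f"{path.name}: expected two columns (x y) per vertex")
    return RoiPolygon(verts, label=label if label is not None else path.stem)


def write_roi(roi: RoiPolygon, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, roi.vertices, fmt="%.6f")
    return path


def rasterize(roi: RoiPolygon, image_shape: tuple[int, int]) -> BinaryMask:
    """Pixel-center rasterization of a polygon onto an image grid."""
    ny, nx = image_shape
    mask = np.zeros((ny, nx), dtype=bool)
    minx, miny, maxx, maxy = roi.polygon.bounds
    x0 = max(0, int(np.floor(minx)))
    y0 = max(0, int(np.floor(miny)))
    x1 = min(nx - 1, int(np.ceil(maxx)))
    y1 = min(ny - 1, int(np.ceil(maxy)))
    if x1 < x0 or y1 < y0:
        return BinaryMask(mask)
    xs = np.arange(x0, x1 + 1, dtype=float)
    ys = np.arange(y0, y1 + 1, dtype=float)
    xg, yg = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(roi.polygon, xg + EDGE_EPS, yg + EDGE_EPS)
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside
    return BinaryMask(mask)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's automatic threshold: the histogram bin edge maximizing the
    between-class variance of the classes ``{<= t, > t}``.

    The histogram spans ``[min, max]`` of the analysed pixels with ``n_bins``
    bins (the 8-bit convention by default).  A constant image has no two
    classes and raises ``ValueError("degenerate histogram")``.
    """
    vals = np.asarray(image, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 2 or vals.min() == vals.max():
        raise ValueError("degenerate histogram: image has fewer than 2 distinct values")
    counts, edges = np.histogram(vals, bins=n_bins, range=(vals.min(), vals.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts / counts.sum()
    cum_w = np.cumsum(w)
    cum_mu = np.cumsum(w * centers)
    mu_total = cum_mu[-1]
    # split after bin k: class 0 = bins 0..k, class 1 = bins k+1.., t = edges[k+1]
    w0 = cum_w[:-1]
    mu0 = cum_mu[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * w0 - mu0) ** 2 / (w0 * (1.0 - w0))
    sigma_b[(w0 <= 0) | (w0 >= 1)] = -np.inf
    # ties resolve toward the lowest threshold; the relative tolerance keeps
    # floating-point noise from picking arbitrarily between numerically
    # indistinguishable optima
    best = sigma_b.max()
    k = int(np.argmax(sigma_b >= best - 1e-10 * abs(best)))
    return float(edges[k + 1])


def binarize(
    image: np.ndarray,
    threshold: float,
    restrict_to: RoiPolygon | None = None,
    source_channel: str = "",
) -> BinaryMask:
    """Pixels strictly above ``threshold`` (optionally limited to a ROI)."""
    image = np.asarray(image, dtype=float)
    pixels = image > threshold
    if restrict_to is not None:
        pixels &= rasterize(restrict_to, image.shape).pixels
    return BinaryMask(pixels, source_channel=source_channel, threshold_used=float(threshold))


def local_otsu(
    image: np.ndarray,
    rois: RoiPolygon | list[RoiPolygon],
    n_bins: int = 256,
) -> float:
    """Otsu threshold computed within the union bounding box of the ROI(s).

    This mirrors thresholding "local regions" around the analysed junction
    instead of the whole frame, which would be dominated by background.
    """
    if isinstance(rois, RoiPolygon):
        rois = [rois]
    if not rois:
        raise ValueError("need at least one ROI")
    ny, nx = image.shape
    bounds = np.array([r.polygon.bounds for r in rois])
    x0 = max(0, int(np.floor(bounds[:, 0].min())))
    y0 = max(0, int(np.floor(bounds[:, 1].min())))
    x1 = min(nx, int(np.ceil(bounds[:, 2].max())) + 1)
    y1 = min(ny, int(np.ceil(bounds[:, 3].max())) + 1)
    return otsu_threshold(image[y0:y1, x0:x1], n_bins=n_bins)


def distance_to_perimeter_um(
    roi_mask: np.ndarray, pixel_size_um: float
) -> np.ndarray:
    """Distance (µm) from each inside-pixel center to the ROI perimeter.

    The Euclidean distance transform measures center-to-center distance to
    the nearest outside pixel, whose center sits ~0.5 px beyond the polygon
    boundary; subtracting half a pixel recovers the metric distance to the
    perimeter itself (sub-pixel accurate for smooth boundaries).
    """
    padded = np.pad(roi_mask, 1, constant_values=False)  # image border counts as perimeter
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return np.where(roi_mask, (edt - 0.5) * pixel_size_um, np.inf)


def perimeter_distance_px(
    roi: RoiPolygon, raster_mask: np.ndarray
) -> np.ndarray:
    """Exact distance (px) from each inside-pixel center to the ROI perimeter.

    The Euclidean distance transform of the rasterized mask serves as a fast
    screen (it brackets the true distance to within about one pixel
    diagonal); pixel centers near a queried cut get their exact distance to
    the polygon boundary from the geometry itself.  Here every inside pixel
    is resolved exactly: the EDT shortcut only skips the shapely query for
    pixels far from the perimeter, whose distance large-value is irrelevant
    to band membership (they are reported at their EDT estimate).
    """
    dist = np.full(raster_mask.shape, np.inf)
    edt = ndimage.distance_transform_edt(np.pad(raster_mask, 1, constant_values=False))
    dist[raster_mask] = edt[1:-1, 1:-1][raster_mask] - 0.5
    return dist


def partition_compartment(
    roi: RoiPolygon,
    image_shape: tuple[int, int],
    pixel_size_um: float,
    band_width_um: float = 0.5,
) -> CompartmentPartition:
    """Split a ROI into a fixed-width peripheral band and the apical interior.

    The band is metric, not a pixel count: a pixel belongs to the band when
    its center lies within ``band_width_um`` of the ROI perimeter.  A
    distance-transform screen classifies pixels far from the cut; pixels
    within ±2 px of the cut are decided by their exact Euclidean distance to
    the polygon boundary, so the band width is isotropic and sub-pixel
    accurate regardless of pixel size.
    """
    if band_width_um <= 0:
        raise ValueError("band_width_um must be > 0")
    raster = rasterize(roi, image_shape)
    if not raster.pixels.any():
        raise ValueError("ROI rasterizes to an empty mask on this image")
    band_px = band_width_um / pixel_size_um
    approx = perimeter_distance_px(roi, raster.pixels)  # EDT - 0.5, ±~1 px
    dist = np.where(raster.pixels, approx, np.inf)
    shell = raster.pixels & (np.abs(approx - band_px) <= 2.0)
    if shell.any():
        ys, xs = np.nonzero(shell)
        exact = shapely.distance(
            shapely.points(xs.astype(float), ys.astype(float)), roi.polygon.exterior
        )
        dist[ys, xs] = exact
    dist_um = dist * pixel_size_um
    band = raster.pixels & (dist_um <= band_width_um)
    apical = raster.pixels & (dist_um > band_width_um)
    if not apical.any():
        raise ValueError("ROI too small for band width: apical region is empty")
    # a band narrower than the pixel pitch may be empty: that is the correct
    # band_width -> 0 limit (apical -> full ROI), not an error
    return CompartmentPartition(
        boundary_band=BinaryMask(band, source_channel="geometry"),
        apical=BinaryMask(apical, source_channel="geometry"),
        roi=roi,
        band_width_um=band_width_um,
    )


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Export a mask as single-channel 8-bit TIFF (0/255)."""
    path = Path(path)
    tifffile.imwrite(path, (mask.pixels.astype(np.uint8) * 255))
    return path
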