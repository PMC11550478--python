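"""Calibrated image-stack input/output and Z flattening.

The universal in-memory container is :class:`ImageStack`: a ``(T, C, Y, X)``
(or ``(T, C, Z, Y, X)`` while a Z axis is still present) intensity array with
an isotropic in-plane pixel size in micrometres and a frame interval in
seconds.  Axis convention is fixed as ``T, C, Z, Y, X``; coordinates are
0-based with pixel centers at integer coordinates and Y increasing downward.

Stacks are read from TIFF / OME-TIFF via :mod:`tifffile`.  Calibration is
taken from OME or ImageJ metadata unless explicitly overridden; an explicit
override always wins (with a logged warning on conflict).  Tabular output is
RFC-4180 CSV via pandas; radial-velocity heat maps are rendered on a
symmetric diverging colour scale centred at zero.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np
import pandas as pd
import tifffile

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

logger = logging.getLogger(__name__)

AXES = "TCZYX"


@dataclass
class ImageStack:
    """A calibrated ``(T, C, Y, X)`` or ``(T, C, Z, Y, X)`` intensity stack.

    Parameters
    ----------
    data:
        Intensity array, arbitrary non-negative units, all values finite.
    pixel_size_um:
        Isotropic in-plane pixel size, µm per pixel (> 0).
    frame_interval_s:
        Seconds between consecutive frames; must be > 0 when T > 1.
    channel_names:
        One label per channel (defaulted to ``ch0, ch1, ...``).
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float = 0.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (4, 5):
            raise ValueError(
                f"data must be (T, C, Y, X) or (T, C, Z, Y, X); got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("stack intensities must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.n_frames > 1 and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0 when T > 1")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal channel count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def has_z(self) -> bool:
        return self.data.ndim == 5

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * float(self.frame_interval_s)

    def frame(self, t: int, c: int) -> np.ndarray:
        """Single-channel 2-D frame (requires a flattened stack)."""
        if self.has_z:
            raise ValueError("stack still has a Z axis; apply project_z first")
        return self.data[t, c]


def _expand_to_tczyx(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder/expand an array with labelled axes into full (T, C, Z, Y, X)."""
    axes = axes.upper()
    if len(axes) != arr.ndim:
        raise ValueError(f"axes string {axes!r} does not match array rank {arr.ndim}")
    unknown = set(axes) - set(AXES)
    if unknown:
        raise ValueError(
            f"ambiguous axis order: unrecognised axes {sorted(unknown)} in {axes!r}; "
            "pass an explicit axes= specification (letters from TCZYX)"
        )
    if len(set(axes)) != len(axes):
        raise ValueError(f"repeated axis letter in {axes!r}")
    for ax in "YX":
        if ax not in axes:
            raise ValueError(f"axes {axes!r} lacks required axis {ax}")
    for ax in AXES:
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in AXES]
    return np.transpose(arr, order)


def _ome_calibration(ome_xml: str) -> tuple[float | None, float | None]:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None, None
    ns = root.tag.split("}")[0] + "}" if root.tag.startswith("{") else ""
    px = root.find(f".//{ns}Pixels")
    if px is None:
        return None, None
    size = px.get("PhysicalSizeX")
    dt = px.get("TimeIncrement")
    return (
        float(size) if size is not None else None,
        float(dt) if dt is not None else None,
    )


def read_stack(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    axes: str | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF as an :class:`ImageStack`.

    Axis order is taken from file metadata; plain TIFFs without usable axis
    metadata require an explicit ``axes`` string (e.g. ``"TCYX"``).  A Z axis
    with more than one plane is preserved for :func:`project_z`.  Metadata
    calibration is used unless overridden; conflicts resolve in favour of the
    explicit override with a warning.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        file_axes = series.axes
        meta_px: float | None = None
        meta_dt: float | None = None
        if tif.ome_metadata:
            meta_px, meta_dt = _ome_calibration(tif.ome_metadata)
        elif tif.imagej_metadata:
            ij = tif.imagej_metadata
            meta_dt = ij.get("finterval")
            page = tif.pages[0]
            xres = page.tags.get("XResolution")
            unit = ij.get("unit", "")
            if xres is not None and unit in ("um", "µm", "micron", "micrometer"):
                num, den = xres.value
                if num:
                    meta_px = den / num

    use_axes = axes if axes is not None else file_axes
    try:
        data = _expand_to_tczyx(arr, use_axes)
    except ValueError as exc:
        if axes is None:
            raise ValueError(
                f"cannot interpret axis order {file_axes!r} of {path.name}: {exc}. "
                "Pass axes= explicitly."
            ) from None
        raise

    if pixel_size_um is not None and meta_px is not None and not math.isclose(
        pixel_size_um, meta_px, rel_tol=1e-6
    ):
        logger.warning(
            "pixel size override %.6g µm replaces metadata value %.6g µm for %s",
            pixel_size_um, meta_px, path.name,
        )
    if frame_interval_s is not None and meta_dt is not None and not math.isclose(
        frame_interval_s, meta_dt, rel_tol=1e-6
    ):
        logger.warning(
            "frame interval override %.6g s replaces metadata value %.6g s for %s",
            frame_interval_s, meta_dt, path.name,
        )

    px = pixel_size_um if pixel_size_um is not None else meta_px
    dt = frame_interval_s if frame_interval_s is not None else meta_dt
    if px is None:
        raise ValueError(
            f"{path.name} carries no pixel-size metadata; pass pixel_size_um explicitly"
        )
    if dt is None:
        if data.shape[0] > 1:
            raise ValueError(
                f"{path.name} carries no frame-interval metadata; pass frame_interval_s"
            )
        dt = 0.0
    if px <= 0 or (data.shape[0] > 1 and dt <= 0):
        raise ValueError("calibration overrides must be positive")

    if data.shape[2] == 1:  # drop trivial Z axis
        data = data[:, :, 0]
    return ImageStack(
        data=data,
        pixel_size_um=float(px),
        frame_interval_s=float(dt),
        channel_names=list(channel_names) if channel_names else [],
    )


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an :class:`ImageStack` as OME-TIFF with calibration metadata."""
    path = Path(path)
    axes = "TCZYX" if stack.has_z else "TCYX"
    metadata = {
        "axes": axes,
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
        "Channel": {"Name": stack.channel_names},
    }
    if stack.n_frames > 1:
        metadata["TimeIncrement"] = stack.frame_interval_s
        metadata["TimeIncrementUnit"] = "s"
    tifffile.imwrite(path, stack.data, ome=True, metadata=metadata)
    return path


def project_z(stack: ImageStack, method: str = "max") -> ImageStack:
    """Flatten the Z axis by maximum or sum slice-intensity projection."""
    if not stack.has_z:
        raise ValueError("stack has no Z axis to project")
    if method == "max":
        data = stack.data.max(axis=2)
    elif method == "sum":
        dtype = np.int64 if np.issubdtype(stack.data.dtype, np.integer) else None
        data = stack.data.sum(axis=2, dtype=dtype)
    else:
        raise ValueError(f"unknown projection method {method!r} (use 'max' or 'sum')")
    return ImageStack(
        data=data,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        channel_names=list(stack.channel_names),
    )


def write_table(records, path: str | Path) -> Path:
    """Write records (list of dicts or DataFrame) to CSV with a header row."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            raise ValueError("refusing to write an empty table")
        df = pd.DataFrame.from_records(records)
    if df.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_heatmap(
    matrix: np.ndarray,
    path: str | Path,
    vlim: float | None = None,
    cmap: str = "RdBu_r",
    upscale: int = 16,
) -> Path:
    """Render a signed matrix as a PNG on a diverging scale centred at zero.

    Positive (outward) values map to warm colours, negative (inward) to cool;
    NaN entries (missing/invalid windows) render grey.  ``vlim`` sets the
    symmetric colour limit; by default the largest absolute finite value.
    """
    matrix = np.asarray(matrix, dtype=float)
    finite = np.isfinite(matrix)
    if matrix.size == 0 or not finite.any():
        raise ValueError("heat map matrix has no finite values")
    if vlim is None:
        vlim = float(np.abs(matrix[finite]).max())
        if vlim == 0:
            vlim = 1.0
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad(color="0.5")
    big = np.kron(matrix, np.ones((upscale, upscale)))
    path = Path(path)
    plt.imsave(path, np.ma.masked_invalid(big), cmap=cm, vmin=-vlim, vmax=vlim)
    return path
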