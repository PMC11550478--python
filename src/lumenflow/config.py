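"""Run configuration: a single human-readable YAML file, validated up front.

Every pipeline run is described by a :class:`RunConfig` naming the input
(either a synthetic preset or a stack plus ROI polygon files), the analyses
to perform, and the stage parameters.  ``validate`` returns an explicit list
of violations — each naming the offending field — and a run only starts when
that list is empty.  CLI flags override config fields (flag > file > default).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .synthetic import PRESET_NAMES

ANALYSES = ("dice", "ba_ratio", "cv", "profile", "piv", "recovery", "all")
SUBPIXEL_MODES = ("gauss3", "parabolic", "none")
PROJECTIONS = ("max", "sum")


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


@dataclass
class RunConfig:
    """Parameters of one pipeline run."""

    output_dir: str = ""
    analysis: str = "all"
    # input: exactly one of preset / stack
    preset: str | None = None
    stack: str | None = None
    axes: str | None = None
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    projection: str | None = None  # required when the stack has a Z axis
    rois: dict[str, str] = field(default_factory=dict)  # name -> polygon file
    # stage parameters
    channel: int = 0
    band_width_um: float = 0.5
    piv_window_px: int = 32
    piv_overlap_px: int = 16
    piv_subpixel: str = "gauss3"
    piv_min_peak_ratio: float = 1.2
    piv_min_mean_intensity: float = 0.0
    radial_interval_s: float = 120.0
    recovery_fraction: float = 0.9
    t_convert_s: float | None = None
    seed: int | None = None
    force: bool = False
    # original file text, echoed verbatim into the output bundle
    source_text: str | None = field(default=None, repr=False, compare=False)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("source_text", None)
        return d


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration; unknown keys are hard errors."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path.name}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)} - {"source_text"}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"{path.name}: unknown config fields {unknown}")
    return RunConfig(**data, source_text=text)


def validate(config: RunConfig) -> list[str]:
    """Return the list of constraint violations (empty iff a run may start)."""
    v: list[str] = []
    if config.analysis not in ANALYSES:
        v.append(f"analysis: unknown analysis {config.analysis!r}; choose from {ANALYSES}")
    if not config.output_dir:
        v.append("output_dir: required")
    if (config.preset is None) == (config.stack is None):
        v.append("preset/stack: exactly one input source must be given")
    if config.preset is not None and config.preset not in PRESET_NAMES:
        v.append(f"preset: unknown preset {config.preset!r}; choose from {PRESET_NAMES}")
    if config.stack is not None and not Path(config.stack).is_file():
        v.append(f"stack: file not found: {config.stack}")
    for name, p in config.rois.items():
        if not Path(p).is_file():
            v.append(f"rois.{name}: file not found: {p}")
    if config.projection is not None and config.projection not in PROJECTIONS:
        v.append(f"projection: must be one of {PROJECTIONS}")
    if config.pixel_size_um is not None and config.pixel_size_um <= 0:
        v.append("pixel_size_um: must be > 0")
    if config.frame_interval_s is not None and config.frame_interval_s <= 0:
        v.append("frame_interval_s: must be > 0")
    if config.channel < 0:
        v.append("channel: must be >= 0")
    if config.band_width_um <= 0:
        v.append("band_width_um: must be > 0")
    if config.piv_window_px < 8:
        v.append("piv_window_px: must be >= 8")
    if not 0 <= config.piv_overlap_px < config.piv_window_px:
        v.append("piv_overlap_px: must satisfy 0 <= overlap < window")
    if config.piv_subpixel not in SUBPIXEL_MODES:
        v.append(f"piv_subpixel: must be one of {SUBPIXEL_MODES}")
    if config.piv_min_peak_ratio < 1.0:
        v.append("piv_min_peak_ratio: must be >= 1")
    if config.piv_min_mean_intensity < 0:
        v.append("piv_min_mean_intensity: must be >= 0")
    if config.radial_interval_s <= 0:
        v.append("radial_interval_s: must be > 0")
    if not 0 < config.recovery_fraction < 1:
        v.append("recovery_fraction: must lie strictly between 0 and 1")
    if config.t_convert_s is not None and config.t_convert_s < 0:
        v.append("t_convert_s: must be >= 0")
    if config.stack is not None and config.analysis == "recovery" and (
        "converted" not in config.rois or "unconverted" not in config.rois
    ):
        v.append("rois: recovery analysis on a stack needs 'converted' and 'unconverted' ROIs")
    return v
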