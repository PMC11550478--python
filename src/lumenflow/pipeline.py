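"""Config-driven orchestration of the analysis stages.

``run`` validates a :class:`~lumenflow.config.RunConfig`, materializes the
input (a synthetic preset scene or a stack read from disk), executes the
requested analyses, and leaves a reproducible output bundle: tidy CSVs,
rendered heat/arrow maps, a log of every parameter actually used, a verbatim
echo of the configuration, and a manifest with one SHA-256 line per output
file.  Runs are deterministic given config plus seed; an existing non-empty
output directory is refused unless ``force`` is set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import piv as pivmod
from . import quantify, segmentation, stack_io, synthetic
from .config import ConfigError, RunConfig, validate

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class _RunContext:
    stack: stack_io.ImageStack
    rois: dict[str, segmentation.RoiPolygon]
    t_convert_s: float | None
    truth: synthetic.SceneTruth | None = None


def _prepare_input(config: RunConfig) -> _RunContext:
    if config.preset is not None:
        params = synthetic.preset(config.preset)
        if config.seed is not None:
            params = replace(params, seed=config.seed)
        stack, truth = synthetic.generate_scene(params)
        rois = {"ring": truth.roi}
        conv, unconv = synthetic.halfring_rois(params)
        rois["converted"], rois["unconverted"] = conv, unconv
        t_convert = (
            params.conversion.t_convert_s if params.conversion is not None else None
        )
        logger.info("generated preset %r with seed %d", config.preset, params.seed)
        return _RunContext(stack=stack, rois=rois, t_convert_s=t_convert, truth=truth)

    stack = stack_io.read_stack(
        config.stack,
        pixel_size_um=config.pixel_size_um,
        frame_interval_s=config.frame_interval_s,
        axes=config.axes,
    )
    if stack.has_z:
        if config.projection is None:
            raise ConfigError(
                "projection: stack has a Z axis; set projection to 'max' or 'sum'"
            )
        stack = stack_io.project_z(stack, config.projection)
        logger.info("flattened Z axis with %s projection", config.projection)
    rois = {
        name: segmentation.read_roi(path, label=name)
        for name, path in config.rois.items()
    }
    return _RunContext(
        stack=stack, rois=rois, t_convert_s=config.t_convert_s, truth=None
    )


def _require_roi(ctx: _RunContext, name: str) -> segmentation.RoiPolygon:
    if name not in ctx.rois:
        raise ConfigError(f"rois.{name}: required for this analysis")
    return ctx.rois[name]


def _masks_nonempty(*masks: segmentation.BinaryMask) -> bool:
    return any(m.pixels.any() for m in masks)


def _analysis_dice(ctx: _RunContext, config: RunConfig, out: Path) -> None:
    """Per-frame colocalization of the two channels inside the ring ROI."""
    ring = _require_roi(ctx, "ring")
    stack = ctx.stack
    records = []
    for t in range(stack.n_frames):
        row: dict = {"frame": t, "timepoint_s": stack.times_s[t]}
        masks = []
        for c in range(min(2, stack.n_channels)):
            img = stack.frame(t, c)
            try:
                thr = segmentation.local_otsu(img, ring)
            except ValueError:
                thr = np.nan
            row[f"threshold_{stack.channel_names[c]}"] = thr
            masks.append(
                segmentation.binarize(img, thr, restrict_to=ring)
                if np.isfinite(thr)
                else segmentation.BinaryMask(np.zeros(stack.frame_shape, bool))
            )
        if len(masks) == 2 and _masks_nonempty(*masks):
            row["dice"] = quantify.dice_coefficient(masks[0], masks[1])
        else:
            row["dice"] = np.nan
        records.append(row)
    stack_io.write_table(records, out / "dice.csv")


def _analysis_ba_ratio(ctx: _RunContext, config: RunConfig, out: Path) -> None:
    ring = _require_roi(ctx, "ring")
    stack = ctx.stack
    part = segmentation.partition_compartment(
        ring, stack.frame_shape, stack.pixel_size_um, config.band_width_um
    )
    records = []
    for t in range(stack.n_frames):
        for c in range(stack.n_channels):
            records.append(
                {
                    "frame": t,
                    "timepoint_s": stack.times_s[t],
                    "channel": stack.channel_names[c],
                    "ba_ratio": quantify.boundary_apical_ratio(stack.frame(t, c), part),
                }
            )
    stack_io.write_table(records, out / "ba_ratio.csv")


def _analysis_cv(ctx: _RunContext, config: RunConfig, out: Path) -> None:
    ring = _require_roi(ctx, "ring")
    stack = ctx.stack
    part = segmentation.partition_compartment(
        ring, stack.frame_shape, stack.pixel_size_um, config.band_width_um
    )
    records = []
    for t in range(stack.n_frames):
        for c in range(stack.n_channels):
            records.append(
                {
                    "frame": t,
                    "timepoint_s": stack.times_s[t],
                    "channel": stack.channel_names[c],
                    "cv": quantify.coefficient_of_variation(
                        stack.frame(t, c), part.apical
                    ),
                }
            )
    stack_io.write_table(records, out / "cv.csv")


def _analysis_profile(ctx: _RunContext, config: RunConfig, out: Path) -> None:
    """Horizontal line profile through the ring centroid, first frame."""
    ring = _require_roi(ctx, "ring")
    stack = ctx.stack
    cx, cy = ring.centroid()
    minx, _, maxx, _ = ring.polygon.bounds
    ny, nx = stack.frame_shape
    pad = 5.0
    x0 = max(1.0, minx - pad)
    x1 = min(nx - 2.0, maxx + pad)
    line = np.array([[x0, cy], [x1, cy]])
    df = None
    for c in range(stack.n_channels):
        s_um, vals = quantify.line_profile(
            stack.frame(0, c), line, width_px=3, pixel_size_um=stack.pixel_size_um
        )
        if df is None:
            df = pd.DataFrame({"arclength_um": s_um})
        df[stack.channel_names[c]] = vals
    stack_io.write_table(df, out / "line_profile.csv")


def _analysis_piv(ctx: _RunContext, config: RunConfig, out: Path) -> None:
    stack = ctx.stack
    if stack.n_frames < 2:
        raise ConfigError("analysis: PIV requires at least two frames")
    ring = _require_roi(ctx, "ring")
    part = segmentation.partition_compartment(
        ring, stack.frame_shape, stack.pixel_size_um, config.band_width_um
    )
    ys, xs = np.nonzero(part.apical.pixels)
    center = (float(xs.mean()), float(ys.mean()))  # apical-centroid convention
    logger.info("PIV center (apical centroid): (%.2f, %.2f) px", *center)

    c = config.channel
    fields = []
    tables = []
    for t in range(stack.n_frames - 1):
        f = pivmod.piv_pair(
            stack.frame(t, c),
            stack.frame(t + 1, c),
            window_px=config.piv_window_px,
            overlap_px=config.piv_overlap_px,
            subpixel=config.piv_subpixel,
            min_peak_ratio=config.piv_min_peak_ratio,
            min_mean_intensity=config.piv_min_mean_intensity,
            time_s=stack.times_s[t],
        )
        fields.append(f)
        df = f.to_dataframe(frame=t)
        rmap = (
            pivmod.radial_project(f, center, stack.pixel_size_um, stack.frame_interval_s)
            if f.n_valid
            else None
        )
        df["radial_um_s"] = rmap.radial.ravel() if rmap is not None else np.nan
        df["tangential_um_s"] = rmap.tangential.ravel() if rmap is not None else np.nan
        tables.append(df)
    stack_io.write_table(pd.concat(tables, ignore_index=True), out / "piv_fields.csv")

    acc = pivmod.heatmap_accumulate(fields, center, stack.pixel_size_um)
    stack_io.write_table(pd.DataFrame(acc.total_um), out / "radial_total_um.csv")
    stack_io.write_table(pd.DataFrame(acc.mean_um), out / "radial_mean_um.csv")
    stack_io.write_heatmap(acc.total_um, out / "radial_total_heatmap.png")
    stack_io.write_heatmap(acc.mean_um, out / "radial_mean_heatmap.png")

    series = pivmod.mean_radial_series(
        fields,
        center,
        stack.pixel_size_um,
        stack.frame_interval_s,
        interval_s=config.radial_interval_s,
    )
    stack_io.write_table(series, out / "mean_radial_series.csv")

    first_valid = next((f for f in fields if f.n_valid), None)
    if first_valid is not None:
        arrows = pivmod.arrow_map(
            first_valid, center, stack.pixel_size_um, stack.frame_interval_s
        )
        stack_io.write_table(arrows, out / "arrow_map.csv")
        pivmod.render_arrow_map(
            arrows,
            out / "arrow_map.png",
            image_shape=stack.frame_shape,
            background=stack.frame(0, c),
        )


def _analysis_recovery(ctx: _RunContext, config: RunConfig, out: Path) -> None:
    if ctx.t_convert_s is None:
        raise ConfigError(
            "t_convert_s: recovery analysis needs the conversion time "
            "(an explicit input, never inferred)"
        )
    conv = _require_roi(ctx, "converted")
    unconv = _require_roi(ctx, "unconverted")
    stack = ctx.stack
    start = int(np.searchsorted(stack.times_s, ctx.t_convert_s - 1e-9))
    green = quantify.halfring_recovery(
        stack, conv, unconv, channel=0, numerator="converted", start_frame=start
    )
    records = [
        {"time_s": t, "ratio": r, "channel": green.channel, "numerator": green.numerator_roi}
        for t, r in zip(green.times_s, green.ratio)
    ]
    summary = [
        {
            "statistic": f"time_to_{config.recovery_fraction:g}_s",
            "value": quantify.time_to_fraction(green, config.recovery_fraction),
        },
        {"statistic": "auc_green", "value": quantify.auc(green)},
    ]
    if stack.n_channels > 1:
        magenta = quantify.halfring_recovery(
            stack, conv, unconv, channel=1, numerator="unconverted", start_frame=start
        )
        records += [
            {
                "time_s": t,
                "ratio": r,
                "channel": magenta.channel,
                "numerator": magenta.numerator_roi,
            }
            for t, r in zip(magenta.times_s, magenta.ratio)
        ]
        summary.append({"statistic": "auc_magenta", "value": quantify.auc(magenta)})
    stack_io.write_table(records, out / "recovery_curves.csv")
    stack_io.write_table(summary, out / "recovery_summary.csv")


_ANALYSES = {
    "dice": _analysis_dice,
    "ba_ratio": _analysis_ba_ratio,
    "cv": _analysis_cv,
    "profile": _analysis_profile,
    "piv": _analysis_piv,
    "recovery": _analysis_recovery,
}


def _select_analyses(config: RunConfig, ctx: _RunContext) -> list[str]:
    if config.analysis != "all":
        return [config.analysis]
    names = ["dice", "ba_ratio", "cv", "profile"]
    if ctx.stack.n_frames >= 2:
        names.append("piv")
    if ctx.t_convert_s is not None and "converted" in ctx.rois and "unconverted" in ctx.rois:
        names.append("recovery")
    return names


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> Path:
    """Execute a validated configuration and return the output bundle path."""
    violations = validate(config)
    if violations:
        raise ConfigError("invalid configuration: " + "; ".join(violations))
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise ConfigError(
            f"output_dir: {out} exists and is not empty; pass force to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("lumenflow")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("effective configuration: %s", json.dumps(config.as_dict(), default=str))
        echo = config.source_text
        if echo is None:
            echo = yaml.safe_dump(config.as_dict(), sort_keys=False)
        (out / "config_echo.yaml").write_text(echo)

        ctx = _prepare_input(config)
        for name in _select_analyses(config, ctx):
            logger.info("running analysis %r", name)
            _ANALYSES[name](ctx, config, out)

        lines = []
        for p in sorted(out.iterdir()):
            if p.name in ("manifest.csv", "run.log") or not p.is_file():
                continue
            lines.append({"name": p.name, "sha256": _sha256(p)})
        stack_io.write_table(lines, out / "manifest.csv")
        logger.info("wrote %d output files", len(lines))
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
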