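"""File formats: multi-page TIFF stacks, CSV tables with '#' metadata
comments, and JSON summaries.

All physical quantities are serialized in um, s and um/min.  Intensity
movies are written as 8-bit TIFF, height maps as 32-bit float (um).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import CorrelationResult, ImageStack, Trajectory, TurnEvent
from .errors import ParameterError

__all__ = [
    "read_stack",
    "write_stack",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_events_csv",
    "read_events_csv",
    "write_correlation",
    "write_json",
]

log = logging.getLogger(__name__)


def read_stack(
    path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
) -> ImageStack:
    """Read a single- or multi-page TIFF as an ImageStack.

    Metadata resolution: explicit arguments (typically from config) win;
    otherwise ImageJ-style TIFF metadata written by :func:`write_stack` is
    used; otherwise 1.0 with a warning.  Conflicts are logged.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        try:
            data = tif.asarray()
        except ValueError as exc:
            raise ParameterError(f"unreadable TIFF (non-uniform pages?): {exc}") from exc
        meta = tif.imagej_metadata or {}
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ParameterError(f"expected 2-D pages, got shape {data.shape}")
    tag_px = meta.get("spacing")
    tag_dt = meta.get("finterval")
    if pixel_size is None:
        pixel_size = float(tag_px) if tag_px else 1.0
        if not tag_px:
            log.warning("%s: no pixel size metadata; assuming 1 um/px", path.name)
    elif tag_px and not np.isclose(float(tag_px), pixel_size):
        log.info("%s: config pixel_size %s overrides TIFF tag %s",
                 path.name, pixel_size, tag_px)
    if frame_interval is None:
        frame_interval = float(tag_dt) if tag_dt else 1.0
        if not tag_dt:
            log.warning("%s: no frame interval metadata; assuming 1 s", path.name)
    elif tag_dt and not np.isclose(float(tag_dt), frame_interval):
        log.info("%s: config frame_interval %s overrides TIFF tag %s",
                 path.name, frame_interval, tag_dt)
    return ImageStack(data, pixel_size=pixel_size, frame_interval=frame_interval)


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as multi-page TIFF with ImageJ-style metadata.

    Integer data is written as 8-bit, float data (height maps) as 32-bit
    float um.
    """
    data = stack.data
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(
        Path(path), data, imagej=True,
        metadata={"spacing": stack.pixel_size, "finterval": stack.frame_interval,
                  "unit": "um"},
    )


def _write_csv_with_comments(path, df: pd.DataFrame, comments: dict) -> None:
    with open(path, "w") as fh:
        for k, v in comments.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def write_trajectory_csv(path, traj: Trajectory, params: dict | None = None) -> None:
    _write_csv_with_comments(path, traj.to_dataframe(), params or {})


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path, comment="#")
    kwargs = {}
    if {"x_smooth_um", "y_smooth_um"} <= set(df.columns):
        kwargs["smooth_xy"] = df[["x_smooth_um", "y_smooth_um"]].to_numpy()
    if "k_per_um" in df.columns:
        kwargs["curvature"] = df["k_per_um"].to_numpy()
    if "k_filtered" in df.columns:
        kwargs["filtered_curvature"] = df["k_filtered"].to_numpy()
    return Trajectory(times=df["time_s"].to_numpy(),
                      raw_xy=df[["x_um", "y_um"]].to_numpy(), **kwargs)


def write_events_csv(path, events, params: dict | None = None) -> None:
    df = pd.DataFrame([
        {"time_s": e.time, "x_um": e.position[0], "y_um": e.position[1],
         "alpha_deg": e.alpha, "k_extremum_per_um": e.k_extremum}
        for e in events
    ])
    if df.empty:
        df = pd.DataFrame(columns=["time_s", "x_um", "y_um", "alpha_deg",
                                   "k_extremum_per_um"])
    _write_csv_with_comments(path, df, params or {})


def read_events_csv(path):
    df = pd.read_csv(path, comment="#")
    return [
        TurnEvent(time=row.time_s, position=(row.x_um, row.y_um),
                  alpha=row.alpha_deg, k_extremum=row.k_extremum_per_um)
        for row in df.itertuples()
    ]


def write_correlation(csv_path, json_path, result: CorrelationResult,
                      extra: dict | None = None) -> None:
    result.to_dataframe().to_csv(csv_path, index=False)
    summary = {
        "primary_peak_lag": result.primary_peak_lag,
        "primary_peak_value": result.primary_peak_value,
        "global_peak_lag": result.global_peak_lag,
        "global_peak_value": result.global_peak_value,
        "convention": "positive lag: first series (x) leads the second (y)",
    }
    if extra:
        summary.update(extra)
    write_json(json_path, summary)


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
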