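"""Quantification of peripheral-ruffle and dorsal-wave dynamics.

Ruffle analysis: active-zone detection by in-band thresholding at the cell
boundary, ROI height/intensity time series, boxcar filtering, oscillation
period from peak spacings, and rectangle geometry (length/width/height) of
thresholded ruffle components.

Dorsal-wave analysis: kymographs along a propagation line, leading-edge
tracing, crest tracking with a linear fit for the propagation speed, and
height/FWHM of 1-D surface profiles.  Cell speed and travelled distance
series are derived from the smoothed trajectory.
"""
from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
from scipy import ndimage, signal
from shapely.geometry import MultiPoint
from skimage.measure import label, regionprops
from skimage.morphology import disk, erosion

from .datatypes import EdgeTrace, ImageStack, Kymograph, Trajectory, WaveMeasurement
from .errors import (
    GeometryError,
    InsufficientDataError,
    ParameterError,
    TraceQualityError,
)

__all__ = [
    "detect_ruffle_zone",
    "make_kymograph",
    "trace_edge",
    "roi_mean_series",
    "boxcar_filter",
    "estimate_period",
    "estimate_wave_speed",
    "measure_ruffle_geometry",
    "measure_dorsal_geometry",
    "speed_and_distance",
    "PeriodEstimate",
    "WaveSpeedEstimate",
]

log = logging.getLogger(__name__)


def detect_ruffle_zone(
    frame: np.ndarray,
    low: float = 70.0,
    high: float = 80.0,
    cell_mask: np.ndarray | None = None,
    annulus_um: float = 2.0,
    pixel_size: float = 1.0,
    min_area_px: int = 5,
) -> np.ndarray:
    """Active ruffle zone: pixels in the [low, high] grayscale band.

    The in-band mask (defaults 70-80 out of 255) is optionally intersected
    with a boundary annulus of the cell mask (``annulus_um`` wide, since
    peripheral ruffles live at the cell edge); components smaller than
    ``min_area_px`` are removed.
    """
    if low > high:
        raise ParameterError("low threshold must not exceed high")
    frame = np.asarray(frame)
    mask = (frame >= low) & (frame <= high)
    if cell_mask is not None:
        r = max(1, int(round(annulus_um / pixel_size)))
        annulus = cell_mask & ~erosion(cell_mask, disk(r))
        mask &= annulus
    if min_area_px > 1 and mask.any():
        mask = _drop_small_components(mask, min_area_px)
    return mask


def _drop_small_components(mask: np.ndarray, min_area_px: int) -> np.ndarray:
    lab = label(mask)
    sizes = np.bincount(lab.ravel())
    keep = np.flatnonzero(sizes >= min_area_px)
    keep = keep[keep > 0]
    return np.isin(lab, keep)


def make_kymograph(
    stack: ImageStack,
    line: tuple,
    width: int = 1,
) -> Kymograph:
    """Sample intensity along a line in every frame (space x time matrix).

    ``line`` is ((x0, y0), (x1, y1)) in um.  Sampling uses bilinear
    interpolation at steps of one pixel size along the line, averaged across
    ``width`` perpendicular pixel offsets.  Row 0 corresponds to the first
    endpoint; column j to frame j.
    """
    (x0, y0), (x1, y1) = line
    px = stack.pixel_size
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length <= 0:
        raise ParameterError("degenerate (zero-length) line")
    _, H, W = stack.data.shape
    for x, y in ((x0, y0), (x1, y1)):
        if not (0 <= x <= W * px and 0 <= y <= H * px):
            raise GeometryError("kymograph line endpoint outside the frame")
    n_s = max(2, int(round(length / px)) + 1)
    s = np.linspace(0.0, length, n_s)
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    nx, ny = -uy, ux  # unit normal
    offsets = (np.arange(width) - (width - 1) / 2.0) * px
    xs = x0 + s[:, None] * ux + offsets[None, :] * nx
    ys = y0 + s[:, None] * uy + offsets[None, :] * ny
    # um -> pixel index (pixel centres at (i + 0.5) * px)
    cols = xs / px - 0.5
    rows = ys / px - 0.5
    coords = np.stack([rows.ravel(), cols.ravel()])
    data = np.empty((n_s, stack.n_frames))
    for j, frame in enumerate(stack.data):
        vals = ndimage.map_coordinates(frame.astype(float), coords, order=1,
                                       mode="nearest")
        data[:, j] = vals.reshape(n_s, width).mean(axis=1)
    return Kymograph(data=data, line=((x0, y0), (x1, y1)),
                     space_step=length / (n_s - 1), time_step=stack.frame_interval)


def trace_edge(
    kymo: Kymograph,
    threshold: float,
    cell_side: str = "low",
    max_missing_frac: float = 0.2,
) -> EdgeTrace:
    """Trace the leading-edge position per time column of a kymograph.

    Each column is binarized at ``threshold``; the cell occupies the
    ``cell_side`` ("low" = position 0) end of the line, and the edge is the
    outer boundary of the above-threshold run attached to that end, thinned
    to a single position per column with sub-pixel refinement by linear
    interpolation of the threshold crossing.  Columns with no cell signal
    are interpolated from their neighbours (logged); more than
    ``max_missing_frac`` missing columns raises ``TraceQualityError``.
    """
    if cell_side not in ("low", "high"):
        raise ParameterError("cell_side must be 'low' or 'high'")
    data = kymo.data if cell_side == "low" else kymo.data[::-1]
    S, T = data.shape
    pos = np.full(T, np.nan)
    for j in range(T):
        col = data[:, j]
        above = col >= threshold
        if not above[0]:
            continue  # no cell at its own side: missing column
        run_end = S - 1 if above.all() else int(np.argmin(above)) - 1
        if run_end < S - 1:
            # sub-pixel crossing between run_end and run_end + 1
            c0, c1 = col[run_end], col[run_end + 1]
            frac = (c0 - threshold) / (c0 - c1) if c0 != c1 else 0.0
            pos[j] = (run_end + frac) * kymo.space_step
        else:
            pos[j] = run_end * kymo.space_step
    missing = np.isnan(pos)
    if missing.mean() > max_missing_frac:
        raise TraceQualityError(
            f"{missing.mean():.0%} of columns have no traceable edge")
    if missing.any():
        idx = np.arange(T)
        pos[missing] = np.interp(idx[missing], idx[~missing], pos[~missing])
        log.warning("interpolated %d missing edge column(s)", int(missing.sum()))
    if cell_side == "high":
        pos = (S - 1) * kymo.space_step - pos
    return EdgeTrace(times=kymo.times.copy(), edge_position=pos)


def roi_mean_series(stack: ImageStack, roi: tuple) -> np.ndarray:
    """Mean pixel value inside a rectangular ROI per frame.

    ``roi`` is (x0, y0, x1, y1) in um; units of the output follow the stack
    (intensity counts or um of height).
    """
    x0, y0, x1, y1 = roi
    px = stack.pixel_size
    _, H, W = stack.data.shape
    c0, c1 = int(np.floor(x0 / px)), int(np.ceil(x1 / px))
    r0, r1 = int(np.floor(y0 / px)), int(np.ceil(y1 / px))
    if not (0 <= c0 < c1 <= W and 0 <= r0 < r1 <= H):
        raise GeometryError(f"ROI {roi} um empty or outside the {W}x{H}px frame")
    return stack.data[:, r0:r1, c0:c1].mean(axis=(1, 2))


def boxcar_filter(series: np.ndarray, npoints: int = 10) -> np.ndarray:
    """Centred moving average over ``npoints``; truncated windows at the ends."""
    series = np.asarray(series, dtype=float)
    if npoints < 1 or npoints > len(series):
        raise ParameterError("npoints must be in [1, len(series)]")
    kernel = np.ones(npoints)
    num = np.convolve(series, kernel, mode="same")
    den = np.convolve(np.ones_like(series), kernel, mode="same")
    return num / den


class PeriodEstimate(NamedTuple):
    period: float
    period_sd: float
    n_peaks: int


def estimate_period(
    series: np.ndarray,
    dt: float,
    min_prominence: float = 0.1,
) -> PeriodEstimate:
    """Oscillation period as the mean spacing of successive peaks.

    Local maxima with prominence of at least ``min_prominence`` times the
    series range are detected; the period is the mean of successive peak
    spacings (in the units of ``dt``), the sd likewise.  Fewer than three
    peaks — e.g. a monotone ramp — raises ``InsufficientDataError``.
    """
    series = np.asarray(series, dtype=float)
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    rng_ = float(np.ptp(series))
    peaks, _ = signal.find_peaks(series, prominence=min_prominence * rng_ if rng_ > 0 else None)
    if len(peaks) < 3:
        raise InsufficientDataError(
            f"only {len(peaks)} peak(s) found; need >= 3 for a period estimate")
    spacings = np.diff(peaks) * dt
    sd = float(np.std(spacings, ddof=1)) if len(spacings) > 1 else 0.0
    return PeriodEstimate(period=float(np.mean(spacings)), period_sd=sd,
                          n_peaks=int(len(peaks)))


class WaveSpeedEstimate(NamedTuple):
    speed: float      # um/min
    speed_sd: float
    n_events: int


def estimate_wave_speed(
    kymo: Kymograph,
    boxcar_n: int = 5,
    min_cols: int = 4,
    stationary_tol: float = 0.05,
) -> WaveSpeedEstimate:
    """Wave propagation speed from the crest locus of a kymograph.

    The crest position per time column is the argmax of the boxcar-smoothed
    spatial profile.  The locus is split into travelling events wherever the
    crest jumps back (a new wave entering); each event spanning at least
    ``min_cols`` columns contributes |slope| of a least-squares line fit to
    crest position vs time, in um/min.  A stationary crest (median advance
    below ``stationary_tol`` um/min) yields speed 0 with a warning.
    """
    prof = np.apply_along_axis(boxcar_filter, 0, kymo.data, min(boxcar_n, kymo.data.shape[0]))
    crest = np.argmax(prof, axis=0) * kymo.space_step
    t = kymo.times
    steps = np.diff(crest)
    med_step = np.median(np.abs(steps))
    direction = np.sign(np.median(steps)) or 1.0
    # a reset: jump against the propagation direction larger than typical advance
    jump = max(5.0 * med_step, 3.0 * kymo.space_step)
    breaks = np.where(steps * direction < -jump)[0] + 1
    segments = np.split(np.arange(len(crest)), breaks)
    speeds = []
    for seg in segments:
        if len(seg) < min_cols:
            continue
        slope = np.polyfit(t[seg], crest[seg], 1)[0]  # um/s
        speeds.append(abs(slope) * 60.0)
    if not speeds:
        raise InsufficientDataError("no travelling crest spanning enough columns")
    speeds = np.asarray(speeds)
    if np.median(speeds) < stationary_tol:
        log.warning("stationary crest: degenerate fit, speed 0")
        return WaveSpeedEstimate(0.0, 0.0, len(speeds))
    sd = float(np.std(speeds, ddof=1)) if len(speeds) > 1 else 0.0
    return WaveSpeedEstimate(float(np.mean(speeds)), sd, len(speeds))


def _component_rectangle(coords_rc: np.ndarray, pixel_size: float) -> tuple:
    """(length, width) um of the minimal-area rectangle around pixel squares."""
    r = coords_rc[:, 0]
    c = coords_rc[:, 1]
    # represent each pixel by its 4 corners so single-pixel-wide shapes have width
    corners = np.concatenate([
        np.stack([c + dc, r + dr], axis=1)
        for dr in (0.0, 1.0) for dc in (0.0, 1.0)
    ]) * pixel_size
    rect = MultiPoint(corners).minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords)
    sides = np.hypot(*np.diff(xy[:3], axis=0).T)
    return float(max(sides)), float(min(sides))


def measure_ruffle_geometry(
    height_stack: ImageStack,
    height_threshold: float,
    min_area_px: int = 4,
) -> tuple:
    """Rectangle geometry of thresholded ruffle components.

    Each frame of the height map is thresholded; every connected component
    (candidate ruffle) is fitted with its minimal-area bounding rectangle:
    length = long side, width = short side; height = per-component maximum
    height.  Returns (WaveMeasurement aggregate, list of per-component
    dicts).  An empty measurement (n=0) is returned when nothing crosses
    the threshold.
    """
    px = height_stack.pixel_size
    records = []
    for i, frame in enumerate(height_stack.data):
        mask = frame > height_threshold
        if min_area_px > 1 and mask.any():
            mask = _drop_small_components(mask, min_area_px)
        if not mask.any():
            continue
        lab = label(mask)
        for prop in regionprops(lab):
            length, width = _component_rectangle(prop.coords.astype(float), px)
            records.append({
                "frame": i,
                "length_um": length,
                "width_um": width,
                "height_um": float(frame[tuple(prop.coords.T)].max()),
                "area_px": int(prop.area),
            })
    if not records:
        return WaveMeasurement(n=0), []
    arr = {k: np.array([r[k] for r in records]) for k in ("length_um", "width_um", "height_um")}

    def _sd(v):
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    meas = WaveMeasurement(
        height=float(arr["height_um"].mean()), height_sd=_sd(arr["height_um"]),
        width=float(arr["width_um"].mean()), width_sd=_sd(arr["width_um"]),
        length=float(arr["length_um"].mean()), length_sd=_sd(arr["length_um"]),
        n=len(records),
    )
    return meas, records


def measure_dorsal_geometry(
    profile: np.ndarray,
    space_step: float = 1.0,
    min_height: float = 0.05,
) -> tuple:
    """Height and FWHM of a single dominant bump in a 1-D surface profile.

    The baseline is the median of the samples outside the central 50% of the
    profile; height = peak - baseline; FWHM is measured at
    baseline + height/2 with linear interpolation between samples.
    Returns (height_um, fwhm_um); raises ``InsufficientDataError`` when the
    peak does not rise ``min_height`` above the baseline.
    """
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    if n < 8:
        raise ParameterError("profile too short")
    q = n // 4
    baseline = float(np.median(np.concatenate([profile[:q], profile[-q:]])))
    ipk = int(np.argmax(profile))
    height = float(profile[ipk]) - baseline
    if height < min_height:
        raise InsufficientDataError("no wave: peak does not rise above baseline")
    half = baseline + height / 2.0

    def _cross(idx_range):
        for i in idx_range:
            lo, hi = profile[i], profile[i + 1]
            if (lo - half) * (hi - half) <= 0 and lo != hi:
                return i + (half - lo) / (hi - lo)
        return None

    left = _cross(range(ipk - 1, -1, -1))
    right = _cross(range(ipk, n - 1))
    if left is None or right is None:
        raise InsufficientDataError("half-maximum level not crossed on both sides")
    return height, float((right - left) * space_step)


def speed_and_distance(
    traj: Trajectory,
    smooth_points: int = 0,
) -> tuple:
    """Cumulative travelled distance (um) and instantaneous speed (um/min).

    Both derive from the smoothed path (falling back to the raw path with a
    warning).  The speed series uses central differences of the positions
    (one-sided at the ends), so each sample is centred on its frame time —
    a backward difference would delay the whole series by half a frame and
    bias any lag measured against it.  ``smooth_points`` > 1 applies a
    boxcar to the speed series.
    """
    xy = traj.smooth_xy
    if xy is None:
        log.warning("no smoothed path; using raw centroids for speed/distance")
        xy = traj.raw_xy
    disp = np.hypot(*np.diff(xy, axis=0).T)
    distance = np.concatenate([[0.0], np.cumsum(disp)])
    dt_min = traj.dt / 60.0
    speed = np.hypot(np.gradient(xy[:, 0]), np.gradient(xy[:, 1])) / dt_min
    if smooth_points and smooth_points > 1:
        speed = boxcar_filter(speed, smooth_points)
    return distance, speed
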