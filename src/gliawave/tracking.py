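"""Centroid tracking and curvature-based turn detection.

The analysis chain for a crawling-cell movie: binarize each frame and keep
the largest connected component as the cell; extract the area centroid per
frame; smooth the centroid trajectory with a sliding 3rd-order polynomial
fit (11-point window, i.e. 150 s at 15-s sampling); compute the signed
planar curvature k(t) of the smoothed path; low-pass k(t) with a 30-s
cutoff; and take the local extrema of the filtered curvature as turning
points, each with its turning angle alpha between the mean headings of the
adjacent runs.
"""
from __future__ import annotations

import logging
import math
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage, signal
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .datatypes import ImageStack, Trajectory, TurnEvent
from .errors import InsufficientDataError, ParameterError, SegmentationError

__all__ = [
    "binarize_frames",
    "extract_centroids",
    "smooth_trajectory",
    "compute_curvature",
    "lowpass_curvature",
    "detect_turns",
    "interturn_stats",
    "align_cell_frames",
    "InterturnStats",
]

log = logging.getLogger(__name__)


def binarize_frames(stack: ImageStack, threshold: float | None = None) -> np.ndarray:
    """Binarize every frame and retain the largest connected component.

    ``threshold`` defaults to per-frame Otsu.  Holes in the retained
    component are filled.  Frames where nothing survives are returned empty
    (all False) and logged; if *all* frames are empty a
    ``SegmentationError`` is raised.
    """
    data = stack.data
    if threshold is not None and np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if not (info.min <= threshold <= info.max):
            raise ParameterError(
                f"threshold {threshold} outside the {data.dtype} intensity range")
    masks = np.zeros(data.shape, dtype=bool)
    n_empty = 0
    for i, frame in enumerate(data):
        thr = threshold
        if thr is None:
            if np.ptp(frame) == 0:
                masks[i] = frame > -np.inf  # uniform frame: everything is foreground
                continue
            thr = threshold_otsu(frame)
        fg = frame > thr
        if not fg.any():
            n_empty += 1
            log.warning("frame %d: empty mask at threshold %s", i, thr)
            continue
        lab = label(fg)
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        masks[i] = ndimage.binary_fill_holes(lab == largest)
    if n_empty == data.shape[0]:
        raise SegmentationError("all frames empty at the given threshold")
    return masks


def extract_centroids(
    masks: np.ndarray,
    pixel_size: float,
    frame_interval: float,
    max_gap: int = 2,
) -> Trajectory:
    """Area centroid of the retained component per frame, in um.

    Empty frames are gaps: runs of up to ``max_gap`` consecutive missing
    centroids are linearly interpolated (logged); longer runs raise
    ``SegmentationError``.  x increases with column index, y with row index
    (image convention); pixel centres sit at (index + 0.5) * pixel_size.
    """
    if pixel_size <= 0 or frame_interval <= 0:
        raise ParameterError("pixel_size and frame_interval must be > 0")
    n = masks.shape[0]
    xy = np.full((n, 2), np.nan)
    for i, m in enumerate(masks):
        if not m.any():
            continue
        props = regionprops(m.astype(np.uint8))
        r, c = props[0].centroid
        xy[i] = ((c + 0.5) * pixel_size, (r + 0.5) * pixel_size)
    missing = np.isnan(xy[:, 0])
    if missing.any():
        runs = _missing_runs(missing)
        worst = max(len(r) for r in runs)
        if missing[0] or missing[-1] or worst > max_gap:
            raise SegmentationError(
                f"unfillable centroid gaps (longest run {worst} frames)")
        idx = np.arange(n)
        for k in range(2):
            xy[missing, k] = np.interp(idx[missing], idx[~missing], xy[~missing, k])
        log.warning("interpolated %d missing centroid frame(s)", int(missing.sum()))
    return Trajectory(times=np.arange(n) * float(frame_interval), raw_xy=xy)


def _missing_runs(missing: np.ndarray) -> list:
    runs, cur = [], []
    for i, m in enumerate(missing):
        if m:
            cur.append(i)
        elif cur:
            runs.append(cur)
            cur = []
    if cur:
        runs.append(cur)
    return runs


def smooth_trajectory(traj: Trajectory, window: int = 11, order: int = 3) -> Trajectory:
    """Sliding local polynomial (Savitzky-Golay) smoothing of the centroid path.

    Each coordinate is replaced by the centre value of a least-squares
    polynomial of degree ``order`` fitted over a sliding window of
    ``window`` points (default 11 points and 3rd order — 150 s at 15-s
    sampling).  At the ends the first/last full window's polynomial is
    evaluated at the off-centre positions, keeping the output length equal
    to the input.
    """
    if window % 2 == 0 or window < 3:
        raise ParameterError("window must be an odd integer >= 3")
    if order >= window:
        raise ParameterError("order must be < window")
    if len(traj) < window:
        raise ParameterError(
            f"trajectory length {len(traj)} shorter than window {window}")
    smooth = np.column_stack([
        signal.savgol_filter(traj.raw_xy[:, k], window, order, mode="interp")
        for k in range(2)
    ])
    return Trajectory(times=traj.times, raw_xy=traj.raw_xy, smooth_xy=smooth,
                      curvature=traj.curvature,
                      filtered_curvature=traj.filtered_curvature)


def compute_curvature(traj: Trajectory) -> np.ndarray:
    """Signed planar curvature k(t) of the smoothed path, in 1/um.

    k = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2), with derivatives by central
    finite differences on the uniform time grid (one-sided at the ends).
    The y axis is flipped to mathematical orientation before differencing so
    that positive k means a counter-clockwise turn in conventional (y-up)
    coordinates.  Samples with vanishing speed get NaN (logged).
    """
    if traj.smooth_xy is None:
        raise ParameterError("smooth the trajectory before computing curvature")
    if len(traj) < 5:
        raise ParameterError("need at least 5 samples for curvature")
    x = traj.smooth_xy[:, 0]
    y = -traj.smooth_xy[:, 1]  # image row axis points down
    dx, dy = np.gradient(x), np.gradient(y)
    ddx, ddy = np.gradient(dx), np.gradient(dy)
    speed2 = dx * dx + dy * dy
    with np.errstate(divide="ignore", invalid="ignore"):
        k = (dx * ddy - dy * ddx) / speed2 ** 1.5
    bad = speed2 < 1e-24
    if bad.any():
        k[bad] = np.nan
        log.warning("curvature undefined at %d zero-speed sample(s)", int(bad.sum()))
    return k


def lowpass_curvature(k: np.ndarray, dt: float, cutoff: float = 30.0) -> np.ndarray:
    """Zero-phase low-pass of the curvature series.

    2nd-order Butterworth with cutoff period ``cutoff`` seconds, applied
    forward-backward (``filtfilt``) so event timing is not shifted.  A
    cutoff period exactly at twice the sampling interval is the Nyquist
    limit: the filter passes the whole band, so the series is returned
    unchanged (logged).  A shorter cutoff is invalid.
    """
    k = np.asarray(k, dtype=float)
    if dt <= 0 or cutoff <= 0:
        raise ParameterError("dt and cutoff must be > 0")
    wn = 2.0 * dt / cutoff
    if wn > 1.0 + 1e-9:
        raise ParameterError(
            f"cutoff {cutoff} s below the Nyquist period {2 * dt} s")
    if wn >= 1.0 - 1e-9:
        log.info("low-pass cutoff at the Nyquist period: series passed unchanged")
        return k.copy()
    b, a = signal.butter(2, wn)
    padlen = min(3 * max(len(a), len(b)), len(k) - 1)
    return signal.filtfilt(b, a, k, padlen=padlen)


class InterturnStats(NamedTuple):
    mean_interval_min: float
    sd_interval_min: float
    mean_alpha_deg: float
    sd_alpha_deg: float
    n_events: int


def _segment_heading(xy: np.ndarray, i0: int, i1: int) -> float:
    """Heading (rad) of the net displacement between samples i0 and i1."""
    d = xy[i1] - xy[i0]
    return math.atan2(d[1], d[0])


def detect_turns(
    traj: Trajectory,
    noise_floor_factor: float = 1.5,
    k_min: float = 0.03,
    alpha_min: float = 3.0,
    extrema_on: str = "signed",
) -> list:
    """Turning points = local extrema of the filtered curvature.

    Extrema (maxima and minima of the signed series by default, or of |k|
    with ``extrema_on="abs"``) must exceed a noise floor of
    max(``noise_floor_factor`` x median |filtered k|, ``k_min``).  For each
    retained extremum the turning angle alpha is the absolute angle between
    the mean heading over the preceding inter-event run and the mean
    heading over the following run (runs bounded by neighbouring extrema or
    the trajectory ends); extrema whose alpha falls below ``alpha_min``
    degrees are discarded as noise wiggles — a genuine turn changes the
    heading persistently, a noise excursion does not.  Extrema at the series
    endpoints are excluded.  An empty list is a valid result.
    """
    if traj.filtered_curvature is None:
        raise ParameterError("filtered curvature required; run the filter first")
    kf = np.asarray(traj.filtered_curvature, dtype=float)
    finite = np.isfinite(kf)
    if not finite.all():
        kf = kf.copy()
        kf[~finite] = 0.0
    rel = noise_floor_factor * float(np.median(np.abs(kf[finite]))) if finite.any() else 0.0
    floor = max(rel, k_min)
    if extrema_on == "abs":
        peaks, _ = signal.find_peaks(np.abs(kf), height=floor)
    else:
        pk_max, _ = signal.find_peaks(kf, height=floor)
        pk_min, _ = signal.find_peaks(-kf, height=floor)
        peaks = np.sort(np.concatenate([pk_max, pk_min]))
    if peaks.size == 0:
        return []
    xy = traj.smooth_xy if traj.smooth_xy is not None else traj.raw_xy
    bounds = np.concatenate([[0], peaks, [len(traj) - 1]])
    events = []
    for j, idx in enumerate(peaks):
        prev_b, next_b = bounds[j], bounds[j + 2]
        if prev_b == idx or next_b == idx:
            continue
        h1 = _segment_heading(xy, prev_b, idx)
        h2 = _segment_heading(xy, idx, next_b)
        alpha = abs(math.degrees(math.atan2(math.sin(h2 - h1), math.cos(h2 - h1))))
        if alpha < alpha_min:
            continue
        events.append(TurnEvent(
            time=float(traj.times[idx]),
            position=(float(xy[idx, 0]), float(xy[idx, 1])),
            alpha=min(alpha, 180.0),
            k_extremum=float(kf[idx]),
        ))
    return events


def interturn_stats(events: Sequence[TurnEvent]) -> InterturnStats:
    """Mean/sd of successive inter-turn intervals (min) and angles (deg)."""
    if len(events) < 2:
        raise InsufficientDataError("need at least 2 events for interval statistics")
    t_min = np.array([e.time for e in events]) / 60.0
    intervals = np.diff(t_min)
    alphas = np.array([e.alpha for e in events])
    sd_int = float(np.std(intervals, ddof=1)) if len(intervals) > 1 else 0.0
    return InterturnStats(
        mean_interval_min=float(np.mean(intervals)),
        sd_interval_min=sd_int,
        mean_alpha_deg=float(np.mean(alphas)),
        sd_alpha_deg=float(np.std(alphas, ddof=1)) if len(alphas) > 1 else 0.0,
        n_events=len(events),
    )


def align_cell_frames(stack: ImageStack, traj: Trajectory, crop_size: float) -> ImageStack:
    """Translate each frame so the centroid sits at the crop centre, then crop.

    Sub-pixel shifts use linear interpolation; regions brought in from
    outside the frame are padded with the frame median (logged when the crop
    exceeds the frame bounds).
    """
    if crop_size <= 0:
        raise ParameterError("crop_size must be > 0")
    if len(traj) != stack.n_frames:
        raise ParameterError("trajectory and stack lengths differ")
    px = stack.pixel_size
    crop_px = int(round(crop_size / px))
    _, H, W = stack.data.shape
    if crop_px > min(H, W):
        log.warning("crop of %d px exceeds %dx%d frame; output padded", crop_px, H, W)
    out = np.empty((stack.n_frames, crop_px, crop_px), dtype=float)
    half = crop_px / 2.0
    pad_r = max(0, crop_px - H)
    pad_c = max(0, crop_px - W)
    for i, frame in enumerate(stack.data):
        cx_px = traj.raw_xy[i, 0] / px - 0.5
        cy_px = traj.raw_xy[i, 1] / px - 0.5
        bg = float(np.median(frame))
        canvas = frame.astype(float)
        if pad_r or pad_c:
            canvas = np.pad(canvas, ((0, pad_r), (0, pad_c)),
                            constant_values=bg)
        # shift so centroid lands at crop centre (half - 0.5 in index space)
        shift = (half - 0.5 - cy_px, half - 0.5 - cx_px)
        shifted = ndimage.shift(canvas, shift, order=1,
                                mode="constant", cval=bg)
        out[i] = shifted[:crop_px, :crop_px]
    if np.issubdtype(stack.data.dtype, np.integer):
        out = np.clip(np.round(out), 0, 255).astype(stack.data.dtype)
    return ImageStack(out, pixel_size=px, frame_interval=stack.frame_interval)
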