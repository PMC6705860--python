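"""Ground-truthed synthetic data for crawling-cell motility and actin waves.

Emulates the statistical structure of time-lapse recordings of freely
crawling microglia so that every downstream stage (tracking, wave kinetics,
correlation) can be tested against known injected parameters:

* run-and-turn centroid trajectories — a renewal process with Gaussian
  inter-turn intervals (mean 1.82 min, sd 0.69 min by default) and Gaussian
  turn angles, with the cell speed alternating between a fast run
  (10 um/min) and a slow run (2 um/min);
* leading-edge ruffle height oscillations (~6.45 s period, ~0.4 um
  amplitude), modelled as a rectified sinusoid: ruffles form and collapse,
  the height never goes negative;
* dorsal actin waves — Gaussian-profile bands (FWHM ~7.4 um) emitted near
  the leading edge every ~1.9 min that travel toward the cell core at
  ~2.5 um/min, coupled to a pulsatile cell speed so that band passage at an
  upstream observation box leads the speed pulse by a known travel time;
* phase-coherent edge oscillations at several leading-edge positions
  (quasi-1-D confined-track condition), with pairwise true lag exactly 0.

Every generator takes all randomness from one seeded ``numpy`` Generator per
call; identical seeds and parameters give bitwise-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .datatypes import EdgeTrace, ImageStack, Kymograph, Trajectory
from .errors import GeometryError, ParameterError

__all__ = [
    "MotilityParams",
    "WaveParams",
    "GroundTruth",
    "gen_trajectory",
    "gen_ruffle_height_series",
    "gen_dorsal_wave_stack",
    "gen_coherent_edges",
    "gen_wave_kymograph",
    "render_cell_movie",
]

# Intensity counts rendered per um of dorsal-surface height, chosen so the
# default 0.48-um dorsal wave peaks at ~120 counts on the 8-bit scale.
COUNTS_PER_UM = 250.0
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # sigma = FWHM / 2.3548


@dataclass
class MotilityParams:
    """Run-and-turn motility parameters.

    Durations in minutes except ``frame_interval`` (seconds); speeds in
    um/min; angles in degrees; lengths in um.
    """

    mean_interturn: float = 1.82
    sd_interturn: float = 0.69
    turn_angle_sd: float = 23.0
    fast_speed: float = 10.0
    slow_speed: float = 2.0
    speed_period: float = 1.82
    total_duration: float = 90.0
    frame_interval: float = 15.0
    positional_noise_sd: float = 0.2
    turn_sign_mode: str = "random"  # "random" or "alternating"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_interturn <= 0 or self.total_duration <= 0 or self.frame_interval <= 0:
            raise ParameterError("durations must be strictly positive")
        if self.sd_interturn < 0 or self.positional_noise_sd < 0 or self.turn_angle_sd < 0:
            raise ParameterError("standard deviations must be non-negative")
        if not (self.fast_speed >= self.slow_speed >= 0):
            raise ParameterError("require fast_speed >= slow_speed >= 0")
        if self.speed_period <= 0:
            raise ParameterError("speed_period must be > 0")
        if self.turn_sign_mode not in ("random", "alternating"):
            raise ParameterError("turn_sign_mode must be 'random' or 'alternating'")


@dataclass
class WaveParams:
    """Actin-wave parameters for both wave classes.

    Ruffle quantities describe the fast peripheral oscillation (period in
    seconds); dorsal quantities the slow travelling band (period in minutes,
    speed in um/min, geometry in um).  ``emission_to_trigger_distance`` is
    the distance between the observation box centre and the downstream point
    whose band arrival triggers the fast-run speed pulse, so the true
    intensity-to-speed lag is that distance divided by ``dorsal_speed``.
    ``noise_sd`` is expressed as a fraction of the relevant amplitude.
    """

    ruffle_period: float = 6.45
    ruffle_amplitude: float = 0.40
    ruffle_width: float = 0.39
    ruffle_length: float = 9.04
    dorsal_period: float = 1.91
    dorsal_speed: float = 2.5
    dorsal_fwhm: float = 7.37
    dorsal_length: float = 46.78
    dorsal_height: float = 0.48
    emission_to_trigger_distance: float = 3.5
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            self.ruffle_period, self.ruffle_amplitude, self.ruffle_width,
            self.ruffle_length, self.dorsal_period, self.dorsal_speed,
            self.dorsal_fwhm, self.dorsal_length, self.dorsal_height,
            self.emission_to_trigger_distance,
        )
        if any(v <= 0 for v in positive):
            raise ParameterError("wave lengths, periods and speeds must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Record of everything injected into a synthetic dataset."""

    true_turn_times: list = field(default_factory=list)   # minutes
    true_turn_angles: list = field(default_factory=list)  # degrees (signed)
    true_period: float | None = None
    true_speed: float | None = None
    true_lag: float | None = None                          # minutes
    event_log: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.true_turn_times, dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ParameterError("turn times must be strictly increasing")


def _truncated_interval_dist(mean: float, sd: float, floor: float):
    """Gaussian inter-turn interval distribution truncated below at ``floor``."""
    if sd == 0:
        return None
    a = (floor - mean) / sd
    return stats.truncnorm(a, np.inf, loc=mean, scale=sd)


def expected_interturn_mean(params: MotilityParams) -> float:
    """Mean of the truncated-Gaussian renewal interval, in minutes."""
    floor = params.frame_interval / 60.0
    dist = _truncated_interval_dist(params.mean_interturn, params.sd_interturn, floor)
    if dist is None:
        return max(params.mean_interturn, floor)
    return float(dist.mean())


def gen_trajectory(params: MotilityParams, seed: int | None = None):
    """Simulate a run-and-turn centroid trajectory.

    The heading is piecewise constant between turn events; events arrive by a
    renewal process with Gaussian(mean_interturn, sd_interturn) waiting times
    truncated below at one frame interval.  At each event the heading changes
    by an angle drawn from N(0, turn_angle_sd); with
    ``turn_sign_mode="alternating"`` the magnitude is drawn the same way but
    the sign strictly alternates.  The instantaneous speed is a square wave
    alternating fast/slow with period ``speed_period``; i.i.d. Gaussian
    positional noise is added to the observed positions.

    Returns
    -------
    (Trajectory, GroundTruth)
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    dt_s = params.frame_interval
    dt_min = dt_s / 60.0
    n = int(round(params.total_duration * 60.0 / dt_s)) + 1
    t_s = np.arange(n) * dt_s
    t_min = t_s / 60.0

    floor = dt_min
    dist = _truncated_interval_dist(params.mean_interturn, params.sd_interturn, floor)
    turn_times: list[float] = []
    t_next = (dist.rvs(random_state=rng) if dist is not None
              else max(params.mean_interturn, floor))
    while t_next < params.total_duration:
        turn_times.append(float(t_next))
        t_next += (dist.rvs(random_state=rng) if dist is not None
                   else max(params.mean_interturn, floor))

    if params.turn_angle_sd > 0:
        deltas = rng.normal(0.0, params.turn_angle_sd, size=len(turn_times))
        if params.turn_sign_mode == "alternating":
            signs = (-1.0) ** np.arange(len(turn_times))
            if len(turn_times) and rng.random() < 0.5:
                signs = -signs
            deltas = np.abs(deltas) * signs
    else:
        deltas = np.zeros(len(turn_times))

    # piecewise-constant heading per frame
    heading0 = rng.uniform(0.0, 2.0 * np.pi)
    headings = np.full(n, heading0)
    for tt, dd in zip(turn_times, deltas):
        headings[t_min >= tt] += math.radians(dd)

    phase = np.mod(t_min, params.speed_period)
    speed = np.where(phase < params.speed_period / 2.0,
                     params.fast_speed, params.slow_speed)

    steps = (speed[:-1] * dt_min)[:, None] * np.stack(
        [np.cos(headings[:-1]), np.sin(headings[:-1])], axis=1)
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    if params.positional_noise_sd > 0:
        xy = xy + rng.normal(0.0, params.positional_noise_sd, size=xy.shape)

    gt = GroundTruth(
        true_turn_times=list(turn_times),
        true_turn_angles=[float(d) for d in deltas],
        event_log=[{"kind": "turn", "time_min": tt, "angle_deg": float(dd)}
                   for tt, dd in zip(turn_times, deltas)],
        extras={"expected_interturn_min": expected_interturn_mean(params),
                "heading0_rad": float(heading0)},
    )
    return Trajectory(times=t_s, raw_xy=xy), gt


def gen_ruffle_height_series(
    params: WaveParams,
    duration: float = 93.0,
    dt: float = 0.2,
    drift: tuple = (0.0, 0.0),
    seed: int | None = None,
):
    """Leading-edge ruffle height oscillation (um) sampled every ``dt`` s.

    Height = amplitude * |sin(pi t / period)| — a rectified sinusoid with
    period ``ruffle_period`` that is never negative (ruffles form, collapse
    and fold back) — plus an optional linear baseline drift from
    ``drift[0]`` to ``drift[1]`` um over the duration, plus Gaussian noise
    of sd ``noise_sd * ruffle_amplitude``.

    Returns (times_s, heights_um, GroundTruth).
    """
    if dt >= params.ruffle_period / 4.0:
        raise ParameterError(
            f"dt={dt} s too coarse to resolve a {params.ruffle_period} s oscillation")
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    h = params.ruffle_amplitude * np.abs(np.sin(np.pi * t / params.ruffle_period))
    h = h + drift[0] + (drift[1] - drift[0]) * (t / duration)
    if params.noise_sd > 0:
        h = h + rng.normal(0.0, params.noise_sd * params.ruffle_amplitude, size=t.shape)
    gt = GroundTruth(true_period=params.ruffle_period,
                     extras={"drift_um": tuple(drift), "dt_s": dt})
    return t, h, gt


def _speed_pulse_train(t_s: np.ndarray, trigger_times_s: Sequence[float],
                       slow: float, fast: float, halfwidth_s: float,
                       amplitudes: Sequence[float] | None = None) -> np.ndarray:
    """Raised-cosine speed pulses centred at trigger times.

    Pulse k peaks at slow + (fast - slow) * amplitudes[k] (amplitudes default
    to 1, i.e. nominal peak ``fast``).
    """
    s = np.full_like(t_s, slow, dtype=float)
    if amplitudes is None:
        amplitudes = np.ones(len(trigger_times_s))
    for tt, ak in zip(trigger_times_s, amplitudes):
        u = (t_s - tt) / halfwidth_s
        w = np.where(np.abs(u) < 1.0, 0.5 * (1.0 + np.cos(np.pi * u)), 0.0)
        s = s + (fast - slow) * ak * w
    return s


def gen_dorsal_wave_stack(
    motility: MotilityParams,
    waves: WaveParams,
    shape: tuple = (128, 128),
    pixel_size: float = 0.5,
    duration_min: float | None = None,
    n_bands: int | None = None,
    cell_axes_um: tuple = (24.0, 14.0),
    band_amplitude_cv: float = 0.3,
    seed: int | None = None,
):
    """Render a dorsal-wave movie coupled to pulsatile cell movement.

    The stack is rendered in the centroid-aligned frame (the frame in which
    the cross-correlation analysis of real recordings is performed): an
    elliptical cell body sits at the image centre, and every
    ``dorsal_period`` minutes a Gaussian-profile band (FWHM ``dorsal_fwhm``
    across the propagation axis, lateral extent ``dorsal_length``, peak
    intensity proportional to ``dorsal_height``) appears just behind the
    leading edge (+x side) and translates toward the cell core at
    ``dorsal_speed``.  When a band reaches the core (the trigger point), the
    cell speed pulses from ``slow_speed`` up toward ``fast_speed`` — a
    raised-cosine pulse centred at the arrival, so the intensity measured in
    an observation box ``emission_to_trigger_distance`` ahead of the trigger
    point leads the speed pulse by exactly
    ``emission_to_trigger_distance / dorsal_speed`` minutes.

    Band strength varies from packet to packet (coefficient of variation
    ``band_amplitude_cv``, mean 1) and each speed pulse scales with its
    band's strength: stronger waves pull harder.  The wave field is
    pre-seeded so it is in steady state at t = 0 (unless ``n_bands``
    restricts emission to the first few bands, e.g. to watch a single crest
    travel).

    Returns
    -------
    (ImageStack, Trajectory, GroundTruth)
        ``GroundTruth.extras["roi_um"]`` holds the observation box
        (x0, y0, x1, y1) in um; ``true_lag`` is in minutes.
    """
    rng = np.random.default_rng(waves.seed if seed is None else seed)
    H, W = shape
    w_um, h_um = W * pixel_size, H * pixel_size
    cx, cy = w_um / 2.0, h_um / 2.0
    a, b = cell_axes_um
    if cx - a < 0 or cy - b < 0:
        raise GeometryError("cell footprint does not fit in the image")

    dt_s = motility.frame_interval
    total_min = motility.total_duration if duration_min is None else duration_min
    n = int(round(total_min * 60.0 / dt_s)) + 1
    t_s = np.arange(n) * dt_s

    v_um_s = waves.dorsal_speed / 60.0
    sigma = waves.dorsal_fwhm * FWHM_TO_SIGMA
    x_front = cx + a
    x_emit = x_front - 2.0          # emission just behind the leading edge
    x_trigger = cx                   # the cell core
    d = waves.emission_to_trigger_distance
    x_roi = x_trigger + d
    if x_emit <= x_roi:
        raise GeometryError(
            "emission point must lie ahead of the observation box; "
            "enlarge the cell or reduce emission_to_trigger_distance")
    if x_emit + 3.0 * sigma > w_um:
        raise GeometryError("band travel span exceeds the image width")

    period_s = waves.dorsal_period * 60.0
    kill_x = x_trigger - waves.dorsal_fwhm  # bands fade out past the core
    if n_bands is not None:
        emit_times = np.arange(0.0, t_s[-1] + period_s, period_s)[:n_bands]
    else:
        # pre-seed emissions so the wave field is in steady state at t = 0
        # (the recording starts mid-crawl, not at wave onset)
        travel_total_s = (x_emit - kill_x) / v_um_s
        n_pre = int(np.ceil(travel_total_s / period_s))
        emit_times = np.arange(-n_pre * period_s, t_s[-1] + period_s, period_s)
    travel_to_trigger_s = (x_emit - x_trigger) / v_um_s
    trigger_times = emit_times + travel_to_trigger_s
    true_lag_min = d / waves.dorsal_speed

    # Wave packets vary in strength from event to event; at the default
    # period/speed/FWHM successive bands overlap heavily, so this
    # band-to-band variability is what makes the point intensity (and the
    # coupled speed) visibly pulsatile at all.
    if band_amplitude_cv > 0:
        band_amps = np.clip(
            rng.normal(1.0, band_amplitude_cv, size=len(emit_times)), 0.3, 1.7)
    else:
        band_amps = np.ones(len(emit_times))

    amp = COUNTS_PER_UM * waves.dorsal_height
    yy, xx = np.mgrid[0:H, 0:W]
    xu = (xx + 0.5) * pixel_size
    yu = (yy + 0.5) * pixel_size
    inside = ((xu - cx) / a) ** 2 + ((yu - cy) / b) ** 2 <= 1.0
    lateral = np.abs(yu - cy) <= waves.dorsal_length / 2.0
    body = np.where(inside, 55.0, 20.0)

    frames = np.empty((n, H, W), dtype=np.uint8)
    for i, t in enumerate(t_s):
        img = body.copy()
        for te, ak in zip(emit_times, band_amps):
            if t < te:
                continue
            xb = x_emit - v_um_s * (t - te)
            if xb < kill_x:
                continue
            band = ak * amp * np.exp(-0.5 * ((xu - xb) / sigma) ** 2)
            img += band * (inside & lateral)
        if waves.noise_sd > 0:
            img += rng.normal(0.0, waves.noise_sd * amp, size=img.shape)
        frames[i] = np.clip(img, 0.0, 255.0).astype(np.uint8)

    pulse_halfwidth_s = min(period_s / 2.0 * 0.8, 45.0)
    keep = trigger_times > -2.0 * pulse_halfwidth_s
    speed = _speed_pulse_train(t_s, trigger_times[keep], motility.slow_speed,
                               motility.fast_speed, pulse_halfwidth_s,
                               amplitudes=band_amps[keep])
    # trapezoidal integration keeps the displacement centred on the interval
    steps = 0.5 * (speed[:-1] + speed[1:]) * (dt_s / 60.0)
    xy = np.zeros((n, 2))
    xy[1:, 0] = np.cumsum(steps)
    if motility.positional_noise_sd > 0:
        xy = xy + rng.normal(0.0, motility.positional_noise_sd, size=xy.shape)

    roi_half = (1.5, 3.0)  # um, along (x, y)
    gt = GroundTruth(
        true_period=waves.dorsal_period,
        true_speed=waves.dorsal_speed,
        true_lag=true_lag_min,
        event_log=(
            [{"kind": "emission", "time_s": float(te), "x_um": x_emit}
             for te in emit_times]
            + [{"kind": "trigger", "time_s": float(tt), "x_um": x_trigger}
               for tt in trigger_times]
        ),
        extras={
            "roi_um": (x_roi - roi_half[0], cy - roi_half[1],
                       x_roi + roi_half[0], cy + roi_half[1]),
            "propagation_line_um": ((x_front, cy), (kill_x, cy)),
            "x_emit_um": x_emit,
            "x_trigger_um": x_trigger,
            "cell_center_um": (cx, cy),
            "cell_axes_um": (a, b),
            "speed_series_um_min": speed,
            "pulse_halfwidth_s": pulse_halfwidth_s,
        },
    )
    stack = ImageStack(frames, pixel_size=pixel_size, frame_interval=dt_s)
    traj = Trajectory(times=t_s, raw_xy=xy)
    return stack, traj, gt


def gen_coherent_edges(
    n_positions: int,
    period: float = 6.45,
    duration: float = 90.0,
    dt: float = 0.2,
    noise_sd: float = 0.1,
    seed: int = 0,
    amplitude: float = 0.4,
    baseline: float = 12.0,
):
    """Phase-coherent leading-edge traces at several positions.

    All traces share one sinusoidal component (common period and common
    random phase, amplitude ``amplitude`` um about ``baseline``); each trace
    then receives independent Gaussian noise of sd ``noise_sd * amplitude``.
    The pairwise true lag is exactly zero — the quasi-1-D confined-track
    condition in which ruffles at left/middle/right edge positions
    oscillate in phase.

    Returns a list of ``EdgeTrace``.
    """
    if n_positions < 2:
        raise ParameterError("need at least two edge positions")
    if dt >= period / 4.0:
        raise ParameterError("dt too coarse to resolve the oscillation")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    common = baseline + amplitude * np.sin(2.0 * np.pi * t / period + phase)
    traces = []
    for _ in range(n_positions):
        noise = rng.normal(0.0, noise_sd * amplitude, size=t.shape) if noise_sd > 0 else 0.0
        traces.append(EdgeTrace(times=t.copy(), edge_position=common + noise))
    return traces


def gen_wave_kymograph(
    speed: float = 2.5,
    fwhm: float = 7.37,
    time_step: float = 15.0,
    n_cols: int = 40,
    length_um: float = 40.0,
    space_step: float = 0.25,
    noise_sd: float = 0.05,
    start_um: float = 2.0,
    seed: int = 0,
) -> Kymograph:
    """Synthetic kymograph with one Gaussian crest translating at ``speed``.

    The crest (FWHM ``fwhm`` um, unit peak) starts at ``start_um`` and
    advances ``speed``/60*``time_step`` um per time column; additive Gaussian
    noise of sd ``noise_sd`` (fraction of the peak) is applied per pixel.
    """
    if speed < 0 or fwhm <= 0:
        raise ParameterError("speed must be >= 0 and fwhm > 0")
    rng = np.random.default_rng(seed)
    s = np.arange(0.0, length_um, space_step)
    t = np.arange(n_cols) * time_step
    sigma = fwhm * FWHM_TO_SIGMA
    crest = start_um + (speed / 60.0) * t
    data = np.exp(-0.5 * ((s[:, None] - crest[None, :]) / sigma) ** 2)
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    line = ((0.0, 0.0), (length_um, 0.0))
    return Kymograph(data=data, line=line, space_step=space_step, time_step=time_step)


def render_cell_movie(
    traj: Trajectory,
    shape: tuple = (192, 192),
    pixel_size: float = 0.5,
    radius_um: float = 8.0,
    foreground: float = 200.0,
    background: float = 30.0,
    noise_sd: float = 0.0,
    recenter: bool = True,
    seed: int = 0,
) -> ImageStack:
    """Render a disk-shaped cell following a trajectory, as an 8-bit movie.

    With ``recenter`` the trajectory is translated so its bounding box sits
    centred in the frame (raising ``GeometryError`` if it cannot fit).  The
    disk centre follows ``raw_xy`` exactly, so centroid re-extraction can be
    compared against the injected path.
    """
    H, W = shape
    w_um, h_um = W * pixel_size, H * pixel_size
    xy = traj.raw_xy.copy()
    if recenter:
        lo, hi = xy.min(axis=0), xy.max(axis=0)
        xy = xy - (lo + hi) / 2.0 + np.array([w_um / 2.0, h_um / 2.0])
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    if (lo < radius_um).any() or (hi[0] > w_um - radius_um) or (hi[1] > h_um - radius_um):
        raise GeometryError("trajectory plus cell radius does not fit in the frame")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:H, 0:W]
    xu = (xx + 0.5) * pixel_size
    yu = (yy + 0.5) * pixel_size
    frames = np.empty((len(traj), H, W), dtype=np.uint8)
    for i, (x, y) in enumerate(xy):
        img = np.where((xu - x) ** 2 + (yu - y) ** 2 <= radius_um ** 2,
                       foreground, background)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return ImageStack(frames, pixel_size=pixel_size, frame_interval=traj.dt)
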