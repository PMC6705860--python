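"""End-to-end pipeline: simulation -> tracking -> wave kinetics -> correlation.

``run_pipeline`` executes the stages in order, writes every intermediate
product (TIFF stacks, CSV tables, JSON summaries) under the configured
output directory, and returns a ``RunManifest`` whose JSON snapshot makes
the run reproducible: config + seed fully determine every output.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, correlation, fileio, synthetic, tracking, wavekinetics
from .config import RunConfig
from .errors import GliawaveError, ParameterError

__all__ = ["RunManifest", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    outputs: dict = field(default_factory=dict)
    stage_params: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: RunConfig, output_dir=None) -> RunManifest:
    """Run the full analysis chain and write all products.

    With no ``input_stack`` the run is simulation-driven: a run-and-turn
    trajectory (turn statistics) and a coupled dorsal-wave movie
    (wave kinetics + correlation) are generated from the configured
    parameters and seed.  Any stage failure aborts with the stage name in
    the error message; products of completed stages remain on disk.
    """
    config.validate()
    config.audit_defaults()
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__,
                           seed=config.seed)

    stage = "simulate"
    try:
        if config.input_stack:
            stack = fileio.read_stack(config.input_stack,
                                      pixel_size=config.acquisition.pixel_size_um,
                                      frame_interval=config.acquisition.frame_interval_s)
            traj_gt = wave_gt = None
            renewal_traj = None
        else:
            renewal_traj, traj_gt = synthetic.gen_trajectory(
                config.motility, seed=config.seed)
            stack, stack_traj, wave_gt = synthetic.gen_dorsal_wave_stack(
                config.motility, config.wave_params,
                pixel_size=config.acquisition.pixel_size_um,
                seed=config.seed + 1)
            fileio.write_stack(out / "dorsal_stack.tif", stack)
            fileio.write_trajectory_csv(out / "sim_trajectory.csv", renewal_traj,
                                        {"seed": config.seed})
            fileio.write_json(out / "ground_truth.json", {
                "true_turn_times_min": traj_gt.true_turn_times,
                "true_turn_angles_deg": traj_gt.true_turn_angles,
                "true_period_min": wave_gt.true_period,
                "true_speed_um_min": wave_gt.true_speed,
                "true_lag_min": wave_gt.true_lag,
                "roi_um": wave_gt.extras["roi_um"],
            })
            manifest.outputs[stage] = ["dorsal_stack.tif", "sim_trajectory.csv",
                                       "ground_truth.json"]

        stage = "tracking"
        tcfg = config.tracking
        acq = config.acquisition
        if config.input_stack:
            masks = tracking.binarize_frames(stack, tcfg.threshold)
            traj = tracking.extract_centroids(masks, acq.pixel_size_um,
                                              acq.frame_interval_s)
        else:
            traj = renewal_traj
        traj = tracking.smooth_trajectory(traj, tcfg.window, tcfg.order)
        traj.curvature = tracking.compute_curvature(traj)
        traj.filtered_curvature = tracking.lowpass_curvature(
            traj.curvature, traj.dt, tcfg.cutoff_s)
        events = tracking.detect_turns(traj, tcfg.noise_floor_factor)
        fileio.write_trajectory_csv(out / "trajectory.csv", traj,
                                    {"window": tcfg.window, "order": tcfg.order,
                                     "cutoff_s": tcfg.cutoff_s})
        fileio.write_events_csv(out / "events.csv", events,
                                {"noise_floor_factor": tcfg.noise_floor_factor})
        manifest.outputs[stage] = ["trajectory.csv", "events.csv"]
        manifest.stage_params[stage] = {"window": tcfg.window, "order": tcfg.order,
                                        "cutoff_s": tcfg.cutoff_s}
        if len(events) >= 2:
            st = tracking.interturn_stats(events)
            manifest.summary["turns"] = {
                "n_events": st.n_events,
                "mean_interturn_min": st.mean_interval_min,
                "sd_interturn_min": st.sd_interval_min,
                "mean_alpha_deg": st.mean_alpha_deg,
                "sd_alpha_deg": st.sd_alpha_deg,
            }

        stage = "waves"
        wcfg = config.waves
        roi = wcfg.roi or (wave_gt.extras["roi_um"] if wave_gt else None)
        line = wcfg.line or (wave_gt.extras["propagation_line_um"] if wave_gt else None)
        if roi is None or line is None:
            raise ParameterError("waves stage needs an ROI and a line "
                                 "(config or simulation ground truth)")
        intensity = wavekinetics.roi_mean_series(stack, roi)
        smoothed = wavekinetics.boxcar_filter(intensity, min(wcfg.boxcar_n, len(intensity)))
        kymo = wavekinetics.make_kymograph(stack, line)
        speed_est = wavekinetics.estimate_wave_speed(kymo)
        period_est = None
        try:
            period_est = wavekinetics.estimate_period(
                smoothed, dt=stack.frame_interval / 60.0,
                min_prominence=wcfg.min_prominence)
        except GliawaveError as exc:
            log.warning("period estimate unavailable: %s", exc)
        np.savetxt(out / "roi_intensity.csv",
                   np.column_stack([stack.times(), intensity]),
                   delimiter=",", header="time_s,intensity", comments="")
        meas_rows = {
            "period_min": period_est.period if period_est else None,
            "period_sd_min": period_est.period_sd if period_est else None,
            "speed_um_min": speed_est.speed,
            "speed_sd_um_min": speed_est.speed_sd,
            "n_wave_events": speed_est.n_events,
        }
        fileio.write_json(out / "wave_measurements.json", meas_rows)
        manifest.outputs[stage] = ["roi_intensity.csv", "wave_measurements.json"]
        manifest.summary["waves"] = meas_rows

        stage = "correlation"
        ccfg = config.correlation
        if config.input_stack:
            motion_traj = traj
        else:
            # the movie-coupled trajectory, not the free-roaming renewal one
            motion_traj = tracking.smooth_trajectory(
                stack_traj, tcfg.window, tcfg.order)
        _, cell_speed = wavekinetics.speed_and_distance(motion_traj)
        nmin = min(len(intensity), len(cell_speed))
        x = correlation.detrend(intensity[:nmin], ccfg.detrend, ccfg.detrend_param)
        y = correlation.detrend(cell_speed[:nmin], ccfg.detrend, ccfg.detrend_param)
        dt_min = stack.frame_interval / 60.0
        max_lag = min(ccfg.max_lag_min, (nmin - 2) * dt_min / 2)
        res = correlation.cross_correlation(x, y, dt=dt_min, max_lag=max_lag)
        tau, val = correlation.primary_peak(res)
        fileio.write_correlation(out / "xcorr.csv", out / "xcorr.json", res,
                                 {"detrend": ccfg.detrend, "max_lag_min": max_lag})
        manifest.outputs[stage] = ["xcorr.csv", "xcorr.json"]
        manifest.summary["correlation"] = {"primary_peak_lag_min": tau,
                                           "primary_peak_value": val}
    except GliawaveError as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    fileio.write_json(out / "manifest.json", manifest.to_dict())
    return manifest
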