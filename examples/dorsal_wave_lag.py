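"""Dorsal-wave passage leads the cell's movement pulse.

Dorsal actin waves are emitted behind the leading edge every ~1.9 min and
travel toward the cell core at ~2.5 um/min; the cell surges forward when a
wave arrives.  This example renders the coupled movie, measures the wave
intensity in an observation box 3.5 um ahead of the trigger point and the
cell speed from the centroid trajectory, and extracts the lag of the first
positive cross-correlation peak — geometrically 3.5 / 2.5 = 1.4 min.
"""
from gliawave import correlation, synthetic, tracking, wavekinetics

motility = synthetic.MotilityParams(total_duration=60.0)
waves = synthetic.WaveParams(noise_sd=0.1)
stack, traj, truth = synthetic.gen_dorsal_wave_stack(motility, waves, seed=3)

intensity = wavekinetics.roi_mean_series(stack, truth.extras["roi_um"])
traj = tracking.smooth_trajectory(traj)
_, speed = wavekinetics.speed_and_distance(traj)

result = correlation.cross_correlation(
    intensity, speed, dt=stack.frame_interval / 60.0, max_lag=5.0)
tau, value = correlation.primary_peak(result, refine="parabolic")

print(f"true lag      : {truth.true_lag:.2f} min")
print(f"recovered lag : {tau:.2f} min (C = {value:.2f})")
print(f"speed range   : {speed.min():.1f} .. {speed.max():.1f} um/min")
# A positive lag means the intensity series leads the speed series: wave
# passage at the box precedes the movement pulse by the travel time to the
# trigger point.
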