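# Methods

This note documents the models and estimator conventions implemented in
`gliawave`, the choices made where the procedure was genuinely open, and
what the synthetic validation does and does not demonstrate.

## The measurement problem

Freely crawling microglia move as a sequence of straight **runs** broken by
discrete **turns** (inter-turn intervals of roughly 2 min), and two classes
of actin waves accompany this motion: fast **peripheral ruffles** at the
leading edge (period ~6.45 s, height ~0.4 µm, width ~0.4 µm, length
~9 µm) and slow **dorsal waves** — broad bands (height ~0.5 µm, FWHM
~7.4 µm, length ~47 µm) emitted behind the leading edge every ~1.9 min
that travel toward the cell core at ~2.5 µm/min. The analyses quantify
(i) the turns, (ii) the wave kinetics, and (iii) the temporal order between
dorsal-wave passage and the cell's pulsatile movement.

## Trajectory analysis

**Smoothing.** Each coordinate is replaced by the centre value of a
least-squares cubic fitted over a sliding 11-point window (Savitzky–Golay;
150 s at the 15-s frame interval). Endpoints evaluate the first/last full
window off-centre so the output keeps the input length. The filter
reproduces any path that is polynomial of degree ≤ 3 in time exactly.

**Curvature.** Signed planar curvature by central finite differences on the
uniform time grid, in µm⁻¹; the image row axis is flipped to mathematical
orientation first, so positive k is a counter-clockwise bend. Zero-speed
samples yield NaN and are logged. Curvature in *time* on a path traversed
at varying speed is not the same observable as curvature in arc length;
see "Known limitations".

**Curvature low-pass.** Zero-phase 2nd-order Butterworth (forward–backward)
with a 30-s cutoff period. At 15-s sampling the 30-s cutoff *is* the
Nyquist period; the filter then passes the entire band and the series is
returned unchanged (logged). Cutoffs below twice the sampling interval are
rejected.

**Turn detection.** Turning points are the local extrema (maxima and
minima) of the filtered signed curvature. An extremum qualifies if

* |k| exceeds `max(1.5 × median |k_filtered|, 0.03 µm⁻¹)`, and
* its turning angle α is at least 3°.

α is the absolute angle between the net-displacement headings of the
preceding and following inter-event segments. The relative floor adapts to
the cell's overall wiggliness; the absolute floor and the angle gate
suppress noise excursions on straight runs, which change no heading
persistently. On the default synthetic conditions (below) this detector
reports a straight-run false-positive rate of ~0.03/min while recovering
the injected event count within ~5% — a purely relative floor (2× median)
cannot do both, because it scales with the noise itself.

**Inter-turn statistics.** Sample mean/sd of successive event-time
differences (min) and of α (deg), requiring at least two events.

## Wave kinetics

* **Kymographs** sample intensity along a line by bilinear interpolation at
  one-pixel steps, optionally averaged across a perpendicular width;
  columns are frames.
* **Edge tracing** binarizes each column, takes the outer boundary of the
  run attached to the cell side, refines it to sub-pixel precision by
  linear interpolation of the threshold crossing, and interpolates missing
  columns (more than 20% missing is a quality error).
* **Periods** come from mean spacings of prominence-filtered peaks
  (prominence ≥ 10% of the series range by default); at least three peaks
  are required. On noiseless sinusoids the bias is below 2% across periods
  from 2 to 200 s at dt ≤ period/10.
* **Propagation speed** is |slope| of a least-squares line through the
  crest locus (argmax per column of the boxcar-smoothed profile), split
  into events wherever the crest jumps against the propagation direction;
  events spanning ≥ 4 columns contribute; a stationary locus reports 0
  with a warning.
* **Ruffle geometry** thresholds the height map and fits each connected
  component's minimal-area rotated rectangle (components represented by
  their pixel-corner points, so single-pixel-wide shapes keep a finite
  width): length = long side, width = short side, height = per-component
  maximum (the height-at-peak reading of the reported values; a mean-height
  option would read systematically lower).
* **Dorsal profile geometry**: baseline = median of the samples outside the
  central 50% of the profile; height = peak − baseline; FWHM at
  baseline + height/2 by linear interpolation. Matches closed forms for
  Gaussian (2.3548 σ) and triangular bumps to < 2%.
* **Speed/distance** derive from the smoothed path; the speed series uses
  central differences so each sample is centred on its frame time. A
  backward difference would delay the series by half a frame and bias every
  lag measured against it.

## Cross-correlation

C_τ = (1/N) Σᵢ (xᵢ − ⟨x⟩)(yᵢ₊τ − ⟨y⟩)/(σₓσᵧ), with ⟨·⟩ and σ from the full
series (population) and **N the total sample count**; the sum runs over the
overlapping range at each lag. Dividing by the full N makes |C_τ| ≤ 1 a
theorem (Cauchy–Schwarz) at the cost of a mild triangular taper toward
extreme lags — the classic biased-estimator trade-off; the per-lag overlap
count is reported alongside. Normalising by the overlap count instead
would exceed 1 at sparse overlaps (values above 1.4 were measured at
overlap 2), which no bounded correlation should do.

**Sign convention.** A positive peak lag means the *first* argument leads
the second. The pipeline passes wave intensity as `x` and cell speed as
`y`, so the reported positive lag is the time by which wave passage
precedes the movement pulse.

**Primary peak.** First local maximum at τ ≥ 0 (or in a configured window)
that exceeds a significance floor of twice the tapered white-noise sd,
2·√N_overlap/N, and stands out from its surroundings by half that floor
(peak prominence) — otherwise noise wiggles on the flank of a broad peak
would qualify. For symmetric windows (edge coherence) the largest peak is
taken, with ties inside the white-noise band broken toward the smallest
|lag|, because periodic inputs repeat their peak every period. Optional
parabolic refinement through the peak and its two neighbours gives a
sub-sample lag; it is off by default and used where the expected lag (e.g.
1.4 min) is not representable on the lag grid (0.25-min steps at 15-s
sampling).

## Synthetic data: what it emulates

All generators draw from one seeded NumPy generator per call; identical
seeds give bitwise-identical outputs.

**Run-and-turn trajectories.** Turn times form a renewal process with
Gaussian intervals (default mean 1.82 min, sd 0.69 min) truncated below at
one frame interval (15 s) — the shortest observable wait. Turn angles are
zero-mean Gaussian (sd 23°, giving a mean |α| of ~18°); the sign is random
by default, with a strict-alternation mode available since the zigzag sign
process is not otherwise constrained. Speed alternates between a fast run
(10 µm/min) and a slow run (2 µm/min) as a square wave of period 1.82 min;
i.i.d. Gaussian positional noise (0.2 µm) is added to observed positions.
The defaults are the reported summary statistics of the crawling cells;
the renewal/Gaussian forms are the simplest processes matching mean and sd.

**Ruffle oscillation.** Height = amplitude·|sin(πt/P)| (+ optional linear
baseline drift + noise): a rectified sinusoid with period P that never goes
negative — ruffles form and collapse — and spans exactly the amplitude.

**Dorsal-wave movie.** An elliptical cell (semi-axes 24 × 14 µm) rendered
in the centroid-aligned frame at 8-bit intensity (body 55, background 20;
the 70–80 band threshold is meaningful on this scale). Bands with Gaussian
cross-profile (FWHM 7.37 µm, peak ∝ height, 250 counts/µm) appear 2 µm
behind the leading edge every 1.91 min and translate toward the core at
2.5 µm/min; the field is pre-seeded so it is in steady state at t = 0 (the
recording starts mid-crawl). At the default period/speed/FWHM successive
crests are 4.78 µm apart and overlap heavily; identical bands would sum to
a spatially almost flat field with no measurable point oscillation, so —
as in the recordings, where wave packets visibly vary in strength — each
band draws a relative amplitude (cv 0.3, clipped to [0.3, 1.7]). When a
band reaches the core (the trigger point) the cell speed rises from the
slow-run level toward the fast-run level as a raised-cosine pulse *centred
on the arrival* and scaled by that band's amplitude. The symmetric pulse
makes the intensity-to-speed lag exactly the geometric travel time
(3.5 µm / 2.5 µm min⁻¹ = 1.4 min for the default observation box); a
one-sided jump-and-decay would shift the correlation peak later by about
half the decay constant. Position is integrated by the trapezoidal rule so
displacements stay centred on their intervals.

**Coherent edges.** All traces share one sinusoid (common random phase)
plus independent Gaussian noise; the pairwise true lag is exactly 0.

**What passing tests do not show.** The generator has no segmentation
difficulty (clean ellipse on uniform background), no cell-shape change, no
band curvature or direction change, no drift or photobleaching, and
Gaussian noise only. Parameter recovery here validates the estimator
chain, not robustness to real microscopy artefacts.

## Validation conditions and problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the study's own scales: 90-min trajectories at 15-s frames (361 samples),
60-min coupled movies at 128×128 px / 0.5 µm px⁻¹ (241 frames), 90-s edge
traces at 0.2-s steps, kymographs of 40 columns; 20 seeds per stochastic
condition. A full run of suite plus acceptance completes in well under a
minute on one core.

Two estimator-physics effects surfaced during validation and are properties
of the method, not defects: (i) with pulsatile speed the curvature-vs-time
peak shifts toward the slow phase of a turn (the cell spends more time near
the corner on its slow side), spreading apparent event times by ~0.45 min
sd even without noise — the ±30-s timing recovery therefore holds at
constant run speed, while count/interval recovery holds under the full
pulsatile conditions; (ii) the correlation lag medians sit ~5% below the
geometric 1.4 min (triangular taper plus finite-window edge effects), well
inside the ±0.25-min acceptance band.

## Known limitations

* Single-cell analysis only: segmentation keeps the largest connected
  component; collisions, division and multi-cell identity are out of scope.
* Curvature is computed against time, not arc length; with strongly
  pulsatile speed the extremum timing acquires a speed-dependent shift
  (see above). Detection counts and angles are unaffected.
* The turn detector's absolute curvature floor (0.03 µm⁻¹) is tuned to the
  µm/min speed scale of crawling glia; much faster or slower cells warrant
  revisiting it (it is configurable).
* Edge tracing assumes the cell occupies one known side of the kymograph
  line and a single contiguous above-threshold run; filopodial
  fragmentation would need pre-smoothing.
* The correlation significance floor assumes white noise; strongly
  autocorrelated series need surrogate-based significance, which is not
  implemented.
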