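# gliawave

Quantitative analysis of crawling-cell motility and collective actin-wave
dynamics, aimed at time-lapse microscopy of freely crawling microglia (and
similar amoeboid cells). The package covers the three analyses that link
actin waves to the cells' zigzag "run-and-turn" behaviour:

1. **Turn detection from trajectories.** The centroid path is smoothed by a
   sliding 3rd-order polynomial fit (11 points ≙ 150 s at 15-s sampling),
   the signed planar curvature

   k(t) = (x′y″ − y′x″) / (x′² + y′²)^{3/2}

   is computed on the smoothed path and low-passed with a 30-s cutoff;
   the local extrema of the filtered k(t) are the turning points, each with
   its turning angle α between the mean headings of the adjacent runs.

2. **Wave kinetics from image stacks.** Kymographs along configurable
   lines, leading-edge tracing, oscillation periods from peak spacings
   (peripheral ruffles, ~6.45 s), propagation speed from a linear fit to
   kymograph crest loci (dorsal waves, ~2.5 µm/min), and wave geometry:
   minimal-area bounding rectangles for thresholded ruffles, baseline-
   subtracted height and FWHM for 1-D dorsal-wave profiles.

3. **Lagged cross-correlation.** The normalised correlation

   C_τ = (1/N) Σᵢ (xᵢ − ⟨x⟩)(yᵢ₊τ − ⟨y⟩) / (σₓσᵧ)

   with full-series mean/σ and N the total sample count, its first positive
   primary peak (wave intensity leading cell speed by ~1.4 min), and
   pairwise phase-coherence of leading-edge traces (zero lag in confined
   quasi-1-D tracks).

Because live-cell recordings are rarely shareable, a first-class
**synthetic-data generator** reproduces the statistical structure of these
recordings with known ground truth: run-and-turn renewal trajectories,
rectified-sinusoid ruffle oscillations, and dorsal-wave movies in which
Gaussian-profile bands travel toward the cell core and trigger speed
pulses, so every estimator can be validated by parameter recovery.

## Worked example

`examples/dorsal_wave_lag.py` renders a 60-min movie in which dorsal bands
are emitted every 1.91 min and travel at 2.5 µm/min toward the core, with
the cell surging when a band arrives; it then measures the wave intensity
in a box 3.5 µm ahead of the trigger point, the cell speed from the
centroid trajectory, and their cross-correlation:

```
true lag      : 1.40 min
recovered lag : 1.48 min (C = 0.41)
speed range   : 0.5 .. 9.4 um/min
```

The positive lag is the time by which wave passage at the box precedes the
movement pulse — geometrically 3.5 µm / 2.5 µm min⁻¹ = 1.4 min. The speed
range reflects the pulsatile slow-run/fast-run alternation (nominally
2 and 10 µm/min, with band-to-band variability).

The other examples each exercise one capability and print the recovered
versus injected values:

* `run_and_turn_trajectory.py` — turn counts and inter-turn statistics,
* `ruffle_oscillation.py` — ruffle period from a noisy height trace,
* `wave_speed_and_geometry.py` — kymograph crest speed and profile FWHM,
* `edge_coherence_1d.py` — zero-lag coherence of three edge traces.

A thin CLI mirrors the library for shell use
(`gliawave simulate|track|waves|xcorr|run`, see `--help`), and
`gliawave run` executes the whole simulate → track → waves → correlate
pipeline, writing CSV/TIFF/JSON products plus a manifest that makes the
run bit-for-bit reproducible from its config and seed.

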