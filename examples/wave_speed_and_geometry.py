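"""Dorsal-wave propagation speed and cross-profile geometry.

The propagation speed comes from a linear fit to the crest locus of a
kymograph (position of the intensity maximum per time column); the wave's
height and width come from a 1-D surface profile: baseline-subtracted peak
height and full width at half maximum.
"""
import numpy as np

from gliawave import synthetic, wavekinetics

# kymograph with a crest advancing 0.625 um per 15-s column (2.5 um/min)
kymo = synthetic.gen_wave_kymograph(speed=2.5, fwhm=7.37, noise_sd=0.075, seed=4)
est = wavekinetics.estimate_wave_speed(kymo)
print(f"wave speed : {est.speed:.2f} um/min "
      f"(injected 2.5; {est.n_events} travelling event)")

# 1-D height profile of a dorsal wave: 0.48 um high, FWHM 7.37 um
x = np.linspace(-25, 25, 400)
sigma = 7.37 / 2.3548
profile = 0.48 * np.exp(-0.5 * (x / sigma) ** 2)
height, fwhm = wavekinetics.measure_dorsal_geometry(profile, space_step=x[1] - x[0])
print(f"wave height: {height:.2f} um, FWHM: {fwhm:.2f} um (injected 0.48 / 7.37)")
# Both estimates should match the injected values to a few percent; the
# FWHM of a Gaussian of sd sigma is 2.3548 * sigma.
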