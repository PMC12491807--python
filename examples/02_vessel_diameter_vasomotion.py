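"""Track vessel diameter and vasomotion from a perpendicular line scan.

Renders a 10-um vessel oscillating at 0.1 Hz with 10% amplitude, runs
FWHM tracking, cleaning, resampling and the vasomotion summary.
"""

import periflow as pf

cfg = pf.SynthConfig(seed=2, duration=60.0, noise_sd=0.1, pixel_size=1.0)
kym, truth = pf.gen_diameter_kymograph(cfg, d0=10.0, vaso_amp=0.1,
                                       vaso_freq=0.1, edge_blur=1.0)

diam = pf.diameter_from_kymograph(kym, window_lines=50)
diam = pf.clean_trace(diam)
smooth = pf.resample_smooth(diam)
vaso = pf.vasomotion_metrics(diam)

print(f"true diameter          : {truth.base_diameter:.1f} um, "
      f"vasomotion {truth.vasomotion_freq} Hz at {truth.vasomotion_amp:.0%}")
print(f"mean measured diameter : {smooth.values.mean():.2f} um")
print(f"vasomotion frequency   : {vaso.frequency:.1f} oscillations/min")
print(f"vasomotor index (dD/D) : {vaso.vasomotor_index:.3f}")
print(f"PSD peak               : {vaso.peak_freq_hz:.3f} Hz")
# Expect ~10 um mean diameter, 6 oscillations/min, index ~0.2
# (peak-to-trough 2 um over mean 10 um), PSD peak at ~0.1 Hz.
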