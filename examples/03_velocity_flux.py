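"""Blood-cell velocity and flux from a parallel line scan.

Renders dark cell streaks moving at 2 mm/s with Poisson arrivals at
8 cells/s, then measures the streak angle per window (radon-style slope
search) and counts cells at a reference position.
"""

import numpy as np

import periflow as pf

cfg = pf.SynthConfig(seed=3, duration=4.0, noise_sd=0.08, pixel_size=0.5)
kym, truth = pf.gen_velocity_kymograph(cfg, velocity=2.0, flux_rate=8.0)

vel = pf.velocity_from_kymograph(kym)
vel_clean = pf.clean_trace(vel)
flux = pf.flux_from_kymograph(kym)

n_windows = len(vel.values)
n_valid = int((vel.flags == 0).sum())
realized = len(truth.cell_entry_times) / cfg.duration
print(f"true velocity          : 2.0 mm/s, flux {truth.flux_rate} cells/s "
      f"(realized {realized:.1f}/s this draw)")
print(f"measured velocity      : {np.nanmedian(vel.values):.2f} mm/s "
      f"({n_valid}/{n_windows} windows with a detectable streak)")
print(f"measured flux          : {flux.values.mean():.1f} cells/s "
      f"({int(flux.meta['n_cells'])} cells in {cfg.duration:.0f} s)")
print(f"outliers removed       : {vel_clean.meta['n_outliers_removed']}")
# The median window velocity should sit within a few percent of 2 mm/s;
# flux counting runs ~5% low because overlapping cells merge into one run.
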