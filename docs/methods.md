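# Methods

`periflow` implements the desk-side analysis of an in-vivo two-photon
pericyte experiment: calcium signaling of mural cells on brain
microvessels, single-vessel hemodynamics from line scans, stimulus-locked
neurovascular coupling (NVC), and a two-level mixed-model comparison of a
paired pre/post pharmacological treatment. Because such experiments rarely
ship raw movies, the package pairs every analysis stage with a synthetic
generator that emulates the statistical structure of the raw data and
records ground truth, so the whole pipeline is validated by parameter
recovery.

## Data model and conventions

Time is axis 0 everywhere; kymograph lines are 0-indexed; positions are
kept in pixels internally and converted through `pixel_size` (µm/px) only
when reporting. All times are seconds, including the line period
(typical 1.8–4 ms). All randomness flows through explicit
`numpy.random.Generator` objects seeded from one configuration seed; there
is no global RNG state, which is what makes end-to-end reruns
byte-identical.

## Calcium stage

**Unmixing.** Two-channel movies (calcium indicator + plasma label) are
unmixed per pixel with the inverse of a 2×2 mixing matrix; negative
results are clipped at zero since photon counts cannot be negative.

**dF/F₀.** F₀ is the mean of the first 5 s of the trial; basal
fluorescence uses the first 2.5 s. dF/F is always computed from the
unfiltered trace; filtering is for detection only.

**Transient detection.** The dF/F trace is band-pass filtered
(zero-phase Butterworth, default 0.01–2 Hz) and peaks are kept when their
prominence exceeds `k` times a robust noise scale, with a minimum peak
separation of 1 s (two candidates closer than that count once; the higher
wins). The noise scale is 1.4826·MAD of the whole filtered trace rather
than the SD of a trial-start window: a short window is bimodal — pure
noise when it happens to contain no transient, transient-inflated when it
does — which makes the threshold erratic, while the median absolute
deviation is insensitive to sparse transients. The default `k = 3.5` was
calibrated on the generator's reference operating point (6 events/min,
SNR 8): mean rate error −0.7 events/min and mean amplitude error 9%.
Amplitude is read as the maximum of the unfiltered dF/F within ±0.25 s of
the detected peak, which undoes the slight peak shift the band-pass
introduces. All knobs are exposed.

**3-D event detection.** Per-pixel baseline mean and SD come from the
first 5 s; voxels above `mean + k·SD` (default `k = 3`) form 26-connected
components over (x, y, t). Components must span ≥ 2 frames, ≥ 4 voxels,
and touch the vessel structure; the per-ROI frequency is retained
components per minute. A relative SD floor (`10⁻⁶` of the baseline mean)
keeps the rule defined on noise-free input. Note a noise-free movie *with*
events degenerates: exponential transient tails never fall below the
threshold and events merge into one component. This is an artifact of
zero noise, not a detector defect; the recovery guarantees are stated at
SNR ≥ 5.

**Spectral summary.** A plain boxcar periodogram of the full mean-removed
trace (no Welch averaging, so the 0.01 Hz edge of the 0.01–0.5 Hz band
stays resolvable on 60-s trials); the reported peak is the PSD argmax
within the band. The band is considered resolvable when at least two
positive-frequency bins fall inside it.

## Line-scan stage

**FWHM diameter.** Lines are averaged in non-overlapping windows
(default 50 lines). The profile baseline is the mean of the outer 10% of
pixels on each side (robust to an off-center vessel); the profile maximum
is refined by a 3-point parabolic fit unless the profile has a flat top
of three or more samples (a true plateau, where the fit would
overshoot); the diameter is the distance between the outermost half-max
crossings, located sub-pixel by linear interpolation, times the pixel
size. Profiles with no crossing (vessel filling the scan) are flagged
invalid.

**Vasomotion.** The oscillation rate counts diameter peaks with
prominence ≥ 5% of the mean diameter and ≥ 2 s separation, per minute of
trace. The vasomotor index ΔD/D averages peak-to-trough excursions
(peak minus the minimum between neighboring peaks) over detected cycles,
divided by the mean diameter — the peak-to-trough convention makes a pure
sinusoid of relative amplitude `a` score `2a`. The PSD argmax of the
diameter trace in 0.01–0.5 Hz is reported alongside, since an oscillation
*rate* and a spectral *peak* are different summaries of the same rhythm.

**Velocimetry.** Each sliding window (default 40 lines, 75% overlap) is
mean-subtracted and projected along candidate streak directions
`x = x₀ + s·line` — a radon-transform search parameterized by slope
rather than angle. The variance of the projection profile peaks when the
projection runs along the streaks; velocity is `s · pixel_size /
line_period`. Two numerical choices matter:

* *Slope grid.* The variance-peak width in slope is roughly (streak
  width)/(lines the streak spans): constant for shallow streaks,
  proportional to `s` for steep ones (which cross the scan in a few
  lines). A uniform-in-angle grid therefore cannot see fast flow — at
  10 mm/s (0.5 µm px, 2 ms lines) the peak is ~0.01° wide. The coarse
  grid is uniform (0.2 px/line) up to |s| = 4 and geometric (ratio 1.05)
  beyond, followed by two local refinement stages, giving sub-0.1%
  recovery over 0.2–10 mm/s.
* *Support correction.* The profile variance of a column whose
  projection line has only `cnt` in-image samples carries sampling
  variance `var(window)/cnt`; without subtracting it, steep slopes with
  short support win on any data. The corrected score also yields a
  separability measure (peak score over window pixel variance): windows
  whose score falls below 0.2 contain no detectable streak (plasma
  between cells) and are flagged invalid with NaN, rather than reporting
  a bounded-but-meaningless number.

Sign convention: positive velocity is motion toward increasing scan
position; flipping the position axis negates the estimate.

**Flux.** Cells are counted at a reference position (default the scan
center, averaged over ±1 column — cells are several pixels wide, so this
cuts noise without diluting dip depth). The column is thresholded by
Otsu's method, capped at four robust SDs below the plasma level (plain
Otsu lands inside the plasma noise when cells occupy only a few percent
of lines) and re-centred at half contrast; a run of sub-threshold lines
counts as a cell only if it also dips below the deep 4-σ level
(hysteresis), and runs separated by ≤ 2 plasma lines merge. Expected
bias: overlapping cells merge, ≈ −5% at 8 cells/s and 2 mm/s. A column
with zero dynamic range yields an all-invalid trace.

**Cleaning.** Samples flagged invalid upstream are non-measurements and
are dropped (counted in `n_missing`). Measured values outside the
physiological bounds — defaults: diameter (0.5, 50] µm, velocity
[−50, 50] mm/s, flux [0, 500] cells/s — are replaced by the mean of the
two nearest valid samples. Velocity and flux traces then pass a
generalized extreme studentized deviate (Rosner) test, up to 15 outliers
at α = 0.05, with critical values from the t distribution; removals are
recorded. A trace with more than half its measured samples out of bounds
is rejected as unusable. The ESD test detects any number of outliers up
to the cap; the conventional printed "minimum = 2" has no effect on the
sequential procedure itself.

**Resampling.** Linear interpolation onto 10 samples/s, then a centered
moving average spanning 1 s — 11 samples, odd so the filter is symmetric
and phase-free; windows shrink at the endpoints. The frequency response
is the Dirichlet kernel of an 11-point average, which the tests verify
against the closed form.

## NVC stage

Percent change is computed against the mean of the 5-s window immediately
before stimulus onset (the trial-start F₀ and the pre-stimulus baseline
can differ, so calcium traces are re-referenced). The response summary is
the extremum strictly inside the stimulus window: minimum for calcium
(pericytes transiently drop Ca²⁺ during functional hyperemia), maximum
for diameter/velocity/flux. Repeated trials are averaged after
resample/smooth alignment, with the SEM reported. A strict window is
used; a post-stimulus grace period for hemodynamic lag can be emulated by
passing a longer `StimulusEpoch`. Noise moves window extrema outward
(an extreme-value bias), so the stated ±1-percentage-point recovery holds
for smoothed, trial-averaged traces — the same form the summaries are
reported in.

## Statistics

**Normality gate.** Shapiro-Wilk at α = 0.05; failing samples are
natural-log transformed (with a documented shift `log(x + 1 − min x)`
when values are non-positive) and the transform is recorded.

**Mixed model.** `value ~ treatment` with random intercepts for animal
and for unit nested in animal — the minimal structure matching repeated
measures of units within animals — fit by maximum likelihood so that the
model with and without the fixed effect are comparable; the
likelihood-ratio statistic is referred to χ²₁. Wald 95% CIs accompany
the estimate. REML variance components are available via
`include_reml=True`; the default is off because the calibration loops
fit thousands of models and REML adds a third fit without changing the
test. Zero-variance responses and non-finite likelihoods are reported
with a `singular` flag (p = 1) rather than raised. Simulation
calibration at the reference design (7 animals × 6 units × 2 trials per
condition, paired): type-I error 4–5% at α = 0.05, and a unit treatment
effect is recovered without bias.

**Holm.** Step-down sequential Bonferroni in closed form; families are
caller-defined (the pipeline treats its metric panel as one family).
Note the adjustment is *not* idempotent in general (re-adjusting an
adjusted vector can raise values further); it is monotone and never
below the raw p-values.

## Synthetic data: what it does and does not emulate

The generators reproduce: Poisson calcium transients with
instant-rise/exponential-decay kernels (τ = 1 s GCaMP6s-like default,
0.5 s RCaMP-like), optional slow sinusoidal calcium rhythms, spatial
Gaussian transients confined to a vessel-shaped mask, symmetric channel
bleed-through, plateau (or Gaussian) vessel profiles with sinusoidal
vasomotion and area-sampled edges (which keeps plateau FWHM exact at any
sub-pixel placement), dark anti-aliased cell streaks with Poisson
arrivals, multiplicative overlap and stall epochs, smooth stimulus-locked
responses, and Gaussian two-level grouped observations.

Not emulated (by design): optics/PSF blur, photobleaching, motion
artifacts, indicator kinetics beyond the single-exponential decay,
non-Poisson cell spacing (real RBCs interact), hematocrit effects, and
non-Gaussian noise. Passing recovery tests therefore demonstrates the
*algorithms* are correct under the stated noise model, not that the
pipeline is robust to every in-vivo artifact; the paper-side defenses
against those artifacts (manual ROIs, bounds cleaning, ESD outlier
removal) are implemented and tested on the failure modes they target.
The real data's SNR is not published, so noise levels are free
parameters; tests state theirs explicitly (SNR 5–10 depending on stage).

## Problem sizes

Recovery checks run at: velocimetry 1-s kymographs (≈47 windows) per
speed in {0.2, 0.5, 1, 2, 5, 10} mm/s; diameter/vasomotion 60-s scans;
3-D events one 60-s, 128×128, 12-fps movie with 10 planted transients;
flux 20 s at 8 cells/s; mixed-model calibration 1000 null and 500
effect simulations (the acceptance script uses 400/300); Holm 20 000
random triples on a 0.001 grid plus an exhaustive coarse grid in the
tests; NVC five averaged trials; determinism a 2×2-unit cohort run
twice. These sizes were chosen so each estimate's Monte-Carlo error is
well below the tolerance it is compared against.

## Known limitations

* Flux counting undercounts by the overlap fraction (cells merging at
  the reference column); no deconvolution of merged runs is attempted.
* Velocity windows containing no streak are reported as missing rather
  than estimated; sparse flux at fast speeds can leave a minority of
  valid windows, which downstream summaries must (and do) handle via
  medians and interpolation.
* The 3-D detector's threshold is per-pixel Gaussian; structured noise
  (e.g., motion) would need a different null model.
* The LMM layer fits random intercepts only; random slopes are out of
  scope.
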