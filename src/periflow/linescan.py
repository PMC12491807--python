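"""Vessel diameter, blood-cell velocity and flux from line-scan kymographs.

A kymograph is the 2-D image built by repeating a 1-D laser line scan:
rows are successive lines (time), columns are positions along the line.
Perpendicular scans encode the vessel lumen width per line; parallel
scans show moving blood cells as dark streaks whose slope encodes speed.

The stages here are full-width-at-half-maximum diameter tracking,
vasomotion summaries, radon-style streak-angle velocimetry, thresholded
flux counting, physiological-bounds cleaning with a generalized-ESD
outlier pass, and interpolation/smoothing onto a common 10-samples/s
time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal
from skimage.filters import threshold_otsu

from .stats import generalized_esd

__all__ = [
    "Kymograph",
    "HemoTrace",
    "VasomotionSummary",
    "FLAG_OK",
    "FLAG_REPLACED",
    "FLAG_INVALID",
    "DEFAULT_BOUNDS",
    "fwhm_profile",
    "diameter_from_kymograph",
    "vasomotion_metrics",
    "velocity_from_kymograph",
    "flux_from_kymograph",
    "clean_trace",
    "resample_smooth",
]

FLAG_OK = 0
FLAG_REPLACED = 1
FLAG_INVALID = 2

#: physiological validity ranges per trace kind (config-exposed defaults)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "diameter": (0.5, 50.0),   # µm
    "velocity": (-50.0, 50.0),  # mm/s
    "flux": (0.0, 500.0),       # cells/s
}


@dataclass
class Kymograph:
    """Line-scan image ``(line, position)`` with acquisition metadata.

    ``line_period`` is seconds per line (plausible 0.5–10 ms),
    ``pixel_size`` µm per pixel, ``orientation`` whether the scan ran
    perpendicular (diameter) or parallel (velocity/flux) to the vessel.
    """

    data: np.ndarray
    line_period: float
    pixel_size: float
    orientation: str  # "perpendicular" | "parallel"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("kymograph must be 2-D with at least 2 lines")
        if not 0.5e-3 <= self.line_period <= 10e-3:
            raise ValueError("line_period outside the plausible 0.5-10 ms band")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.orientation not in ("perpendicular", "parallel"):
            raise ValueError("orientation must be 'perpendicular' or 'parallel'")

    @property
    def n_lines(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_lines * self.line_period


@dataclass
class HemoTrace:
    """One hemodynamic time series with per-sample quality flags.

    ``kind`` is ``diameter`` (µm), ``velocity`` (mm/s) or ``flux``
    (cells/s). Flags: 0 valid, 1 replaced by neighbor mean, 2 invalid.
    """

    kind: str
    times: np.ndarray
    values: np.ndarray
    flags: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.flags is None:
            self.flags = np.zeros(len(self.values), dtype=np.uint8)
        self.flags = np.asarray(self.flags, dtype=np.uint8)
        if not (len(self.times) == len(self.values) == len(self.flags)):
            raise ValueError("times, values and flags must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        return (self.flags != FLAG_INVALID) & np.isfinite(self.values)


@dataclass
class VasomotionSummary:
    """Vasomotion of a diameter trace: oscillation rate and amplitude.

    ``frequency`` counts detected wall oscillations per minute;
    ``vasomotor_index`` is the mean peak-to-trough excursion divided by
    the mean diameter (ΔD/D); ``peak_freq_hz`` is the PSD argmax in the
    0.01–0.5 Hz band.
    """

    frequency: float
    vasomotor_index: float
    peak_freq_hz: float


# ---------------------------------------------------------------------------
# diameter


def fwhm_profile(profile: np.ndarray, baseline_frac: float = 0.1
                 ) -> tuple[float, bool]:
    """Full width at half maximum of a 1-D intensity profile, in pixels.

    The baseline is the mean of the outer ``baseline_frac`` of pixels on
    each side (robust to an off-center vessel); the half-max level is
    midway between baseline and maximum; the width is the distance
    between the outermost half-max crossings, located to sub-pixel
    precision by linear interpolation. Returns ``(width_px, ok)`` —
    ``ok`` is False when the profile never drops below half-max on one
    side (vessel filling the scan) or never rises above it.
    """
    p = np.asarray(profile, dtype=float)
    n = len(p)
    k = max(int(np.ceil(baseline_frac * n)), 1)
    base = 0.5 * (p[:k].mean() + p[-k:].mean())
    # sub-pixel maximum by 3-point parabolic refinement: the sampled max
    # underestimates a smooth peak that falls between pixels
    im = int(np.argmax(p))
    pmax = p[im]
    run = 1  # flat-top length: parabolic fit is wrong on a true plateau
    while im + run < n and p[im + run] >= pmax - 1e-12 * abs(pmax):
        run += 1
    if 0 < im < n - 1 and run <= 2:
        denom = p[im - 1] - 2 * p[im] + p[im + 1]
        if denom < 0:
            pmax = p[im] - (p[im - 1] - p[im + 1]) ** 2 / (8.0 * denom)
    half = base + (pmax - base) / 2.0
    above = p >= half
    if not above.any():
        return np.nan, False
    i = int(np.argmax(above))            # first above
    j = n - 1 - int(np.argmax(above[::-1]))  # last above
    if i == 0 or j == n - 1:
        return np.nan, False
    xl = (i - 1) + (half - p[i - 1]) / (p[i] - p[i - 1])
    xr = j + (p[j] - half) / (p[j] - p[j + 1])
    return float(xr - xl), True


def diameter_from_kymograph(kym: Kymograph, window_lines: int = 50
                            ) -> HemoTrace:
    """FWHM diameter per block of averaged lines.

    Lines are averaged in non-overlapping windows of ``window_lines``;
    the FWHM of each window-mean profile, times the pixel size, is the
    diameter sample at the window's center time. Windows whose profile
    has no half-max crossing are flagged invalid rather than dropped.
    """
    if kym.orientation != "perpendicular":
        raise ValueError("diameter requires a perpendicular kymograph")
    n_win = kym.n_lines // window_lines
    if n_win < 1:
        raise ValueError("kymograph shorter than one window")
    times = (np.arange(n_win) + 0.5) * window_lines * kym.line_period
    values = np.empty(n_win)
    flags = np.zeros(n_win, dtype=np.uint8)
    for w in range(n_win):
        prof = kym.data[w * window_lines:(w + 1) * window_lines].mean(axis=0)
        width, ok = fwhm_profile(prof)
        values[w] = width * kym.pixel_size if ok else np.nan
        if not ok:
            flags[w] = FLAG_INVALID
    return HemoTrace(kind="diameter", times=times, values=values, flags=flags,
                     meta={"window_lines": window_lines,
                           "pixel_size": kym.pixel_size})


def vasomotion_metrics(d: HemoTrace,
                       min_prominence_frac: float = 0.05,
                       min_separation_s: float = 2.0,
                       psd_band: tuple[float, float] = (0.01, 0.5),
                       ) -> VasomotionSummary:
    """Oscillation rate, vasomotor index (ΔD/D) and PSD peak of a
    diameter trace.

    Wall oscillations are peaks with prominence at least
    ``min_prominence_frac`` of the mean diameter and at least
    ``min_separation_s`` apart; the rate is peaks per minute of trace.
    The vasomotor index averages, over detected cycles, the peak value
    minus the minimum between neighboring peaks, normalized by the mean
    diameter.
    """
    from .calcium import compute_psd_peak  # local import avoids a cycle

    if d.kind != "diameter":
        raise ValueError("vasomotion metrics require a diameter trace")
    ok = d.valid
    if not ok.any():
        raise ValueError("all samples invalid")
    t, v = d.times[ok], d.values[ok]
    if t[-1] - t[0] < 30.0:
        raise ValueError("need at least 30 s of valid diameter samples")
    dt = float(np.median(np.diff(t)))
    duration = len(v) * dt
    mean_d = float(v.mean())

    dist = max(int(round(min_separation_s / dt)), 1)
    peaks, _ = signal.find_peaks(v, prominence=min_prominence_frac * mean_d,
                                 distance=dist)
    freq = len(peaks) / duration * 60.0

    if len(peaks):
        excursions = []
        bounds = np.concatenate([[0], peaks, [len(v) - 1]])
        for pi, pk in enumerate(peaks, start=1):
            lo, hi = bounds[pi - 1], bounds[pi + 1]
            trough = v[lo:hi + 1].min()
            excursions.append(v[pk] - trough)
        index = float(np.mean(excursions)) / mean_d
    else:
        index = 0.0

    peak_hz = compute_psd_peak(v, sampling_rate=1.0 / dt, band=psd_band).peak_freq
    return VasomotionSummary(frequency=freq, vasomotor_index=index,
                             peak_freq_hz=peak_hz)


# ---------------------------------------------------------------------------
# velocity


def _profile_variance(window: np.ndarray, slopes: np.ndarray) -> np.ndarray:
    """Variance of the shear-projection profile for each candidate slope.

    For slope ``s`` (px per line) the projection collects, per launch
    column ``x0``, the mean of samples along the line ``x = x0 + s·l``
    (linear interpolation). At the streak slope the dark bands align
    into the same columns and the profile variance peaks. Columns are
    weighted by their in-bounds sample count, and the expected sampling
    variance of a mean of ``cnt`` pixels (``var(window)/cnt``) is
    subtracted: without that correction, steep slopes — whose projection
    lines have short in-image support — are systematically favored on
    any data, aligned or not.
    """
    nl, npos = window.shape
    w = np.asarray(window - window.mean(), dtype=np.float32)
    lines = np.arange(nl)
    x0 = np.arange(npos, dtype=np.float32)
    xs = x0[None, None, :] + slopes.astype(np.float32)[:, None, None] \
        * lines.astype(np.float32)[None, :, None]
    xf = np.floor(xs).astype(np.int64)
    frac = xs - xf
    valid = (xf >= 0) & (xf < npos - 1)
    xfc = np.clip(xf, 0, npos - 2)
    vals = w[lines[None, :, None], xfc] * (1 - frac) \
        + w[lines[None, :, None], xfc + 1] * frac
    vals = np.where(valid, vals, np.float32(0.0))
    cnt = valid.sum(axis=1)
    prof = (vals.sum(axis=1) / np.maximum(cnt, 1)).astype(np.float64)
    wgt = np.where(cnt >= min(3, nl), cnt, 0).astype(np.float64)
    wsum = wgt.sum(axis=1)
    mu = (prof * wgt).sum(axis=1) / np.maximum(wsum, 1.0)
    sq = (prof - mu[:, None]) ** 2 - float(w.var()) / np.maximum(cnt, 1)
    var = (sq * wgt).sum(axis=1) / np.maximum(wsum, 1.0)
    var[wsum < 8] = 0.0
    return var


def _slope_grid(s_max: float, ds_lin: float = 0.2, s_lin: float = 4.0,
                ratio: float = 1.05) -> np.ndarray:
    """Symmetric slope grid: uniform near zero, geometric beyond.

    The variance-peak width in slope is ~(streak width)/(lines it spans),
    which is roughly constant for shallow streaks and proportional to
    ``s`` for steep ones, so a hybrid uniform+geometric grid guarantees
    the coarse pass lands within the peak at every measurable speed.
    """
    s_lin = min(s_lin, s_max)
    lin = np.arange(0.0, s_lin, ds_lin)
    geo = [s_lin]
    while geo[-1] < s_max:
        geo.append(geo[-1] * ratio)
    pos = np.concatenate([lin, np.asarray(geo)])
    return np.concatenate([-pos[::-1], pos[1:]])


def velocity_from_kymograph(kym: Kymograph,
                            window_lines: int = 40,
                            overlap_fraction: float = 0.75,
                            v_bounds: tuple[float, float] = (-50.0, 50.0),
                            min_separability: float = 0.2) -> HemoTrace:
    """Streak-angle velocimetry on sliding windows of a parallel scan.

    Each mean-subtracted window is projected along candidate streak
    directions (a radon-transform search restricted to the slope family
    ``x = x0 + s·line``); the slope maximizing the projection-profile
    variance gives the velocity ``v = s · pixel_size / line_period``.
    After a coarse pass on a hybrid slope grid, two local refinement
    stages sharpen the estimate well below the grid spacing.

    The per-window separability score (peak corrected variance over the
    window's pixel variance) is stored in ``meta["separability"]``.
    Windows whose best slope sits at the grid boundary (out of the
    measurable range) and windows with no detectable streak (peak score
    below ``min_separability`` of the window variance — plasma-only
    windows between cells) carry NaN and are flagged invalid. Sign
    convention: positive velocity is motion toward increasing scan
    position.
    """
    if kym.orientation != "parallel":
        raise ValueError("velocity requires a parallel kymograph")
    if window_lines < 20:
        raise ValueError("window must span at least 20 lines")
    step = max(int(round(window_lines * (1.0 - overlap_fraction))), 1)
    px_per_mm_s = 1e3 * kym.line_period / kym.pixel_size  # slope per unit velocity
    s_max = max(abs(v_bounds[0]), abs(v_bounds[1])) * px_per_mm_s
    grid = _slope_grid(s_max)

    starts = range(0, kym.n_lines - window_lines + 1, step)
    times, values, flags, sep = [], [], [], []
    for i0 in starts:
        win = np.asarray(kym.data[i0:i0 + window_lines], dtype=float)
        var = _profile_variance(win, grid)
        best = int(np.argmax(var))
        wvar = float(win.var())
        score = float(var[best] / wvar) if wvar > 0 else 0.0
        sep.append(score)
        s0 = grid[best]
        bad = best in (0, len(grid) - 1) or score < min_separability
        if not bad:
            for span, n in ((0.25 + 0.05 * abs(s0), 25),
                            (0.02 + 0.01 * abs(s0), 41)):
                loc = np.linspace(s0 - span, s0 + span, n)
                loc = loc[np.abs(loc) <= s_max]
                v2 = _profile_variance(win, loc)
                s0 = loc[np.argmax(v2)]
        times.append((i0 + window_lines / 2.0) * kym.line_period)
        values.append(np.nan if bad else s0 / px_per_mm_s)
        flags.append(FLAG_INVALID if bad else FLAG_OK)
    return HemoTrace(kind="velocity", times=np.asarray(times),
                     values=np.asarray(values),
                     flags=np.asarray(flags, dtype=np.uint8),
                     meta={"separability": np.asarray(sep),
                           "window_lines": window_lines,
                           "overlap_fraction": overlap_fraction})


# ---------------------------------------------------------------------------
# flux


def flux_from_kymograph(kym: Kymograph, ref_position: Optional[int] = None,
                        bin_s: float = 1.0, min_gap_lines: int = 2,
                        column_halfwidth: int = 1) -> HemoTrace:
    """Blood-cell flux by thresholded counting at a fixed scan position.

    The intensity at the reference column is split into cell/plasma by
    Otsu's threshold on its histogram (cells are dark); plasma→cell
    transitions are counted into ``bin_s``-second bins, with cell runs
    separated by fewer than ``min_gap_lines`` plasma lines merged into
    one cell. A column with no dynamic range yields an all-invalid trace.

    Because cells occupy only a small fraction of the lines at
    physiological flux, Otsu's between-class criterion can land inside
    the plasma noise; the Otsu threshold is therefore capped at four
    robust noise SDs (MAD-based) below the plasma level, and then
    re-centred midway between the plasma level and the median of the
    provisional cell samples, which places it at half contrast where
    noise flicker does not fragment a cell run. A run only counts as a
    cell if it dips below the deep (4-σ) level — a hysteresis pair that
    keeps single-line noise dips from fabricating cells. Noise-free
    columns are unaffected.
    """
    if kym.orientation != "parallel":
        raise ValueError("flux requires a parallel kymograph")
    ref = kym.data.shape[1] // 2 if ref_position is None else ref_position
    lo_c = max(ref - column_halfwidth, 0)
    hi_c = min(ref + column_halfwidth + 1, kym.data.shape[1])
    # averaging a few adjacent columns (cells are several px wide) cuts
    # noise without diluting the dip depth
    col = np.asarray(kym.data[:, lo_c:hi_c], dtype=float).mean(axis=1)
    n_bins = max(int(np.floor(kym.duration / bin_s)), 1)
    times = (np.arange(n_bins) + 0.5) * bin_s
    if np.ptp(col) < 1e-12:
        return HemoTrace(kind="flux", times=times, values=np.zeros(n_bins),
                         flags=np.full(n_bins, FLAG_INVALID, dtype=np.uint8),
                         meta={"reason": "zero dynamic range"})
    plasma = float(np.median(col))
    sigma = 1.4826 * float(np.median(np.abs(col - plasma)))
    prelim = min(threshold_otsu(col), plasma - 4.0 * sigma)
    below = col[col < prelim]
    if len(below):
        thr = max(0.5 * (plasma + float(np.median(below))), prelim)
    else:
        thr = prelim
    cell = col < thr

    # merge runs separated by short plasma gaps, then count run starts,
    # keeping only runs that reach the deep threshold
    idx = np.flatnonzero(cell)
    starts_lines: list[int] = []
    if len(idx):
        gaps = np.diff(idx)
        breaks = np.flatnonzero(gaps > min_gap_lines)
        run_bounds = np.concatenate([[0], breaks + 1, [len(idx)]])
        for b0, b1 in zip(run_bounds[:-1], run_bounds[1:]):
            run = idx[b0:b1]
            if col[run[0]:run[-1] + 1].min() < prelim:
                starts_lines.append(int(run[0]))
    counts = np.zeros(n_bins)
    for s in starts_lines:
        b = int(s * kym.line_period / bin_s)
        if b < n_bins:
            counts[b] += 1
    return HemoTrace(kind="flux", times=times, values=counts / bin_s,
                     meta={"n_cells": len(starts_lines), "bin_s": bin_s})


# ---------------------------------------------------------------------------
# cleaning and resampling


def _replace_deviant(values: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Replace flagged samples with the mean of the two nearest valid ones."""
    out = values.copy()
    good_idx = np.flatnonzero(~bad)
    if len(good_idx) == 0:
        raise ValueError("no valid samples to interpolate from")
    for i in np.flatnonzero(bad):
        order = good_idx[np.argsort(np.abs(good_idx - i), kind="stable")]
        nearest = order[:2] if len(order) >= 2 else order
        out[i] = values[nearest].mean()
    return out


def clean_trace(t: HemoTrace,
                bounds: Optional[tuple[float, float]] = None,
                esd_k_max: int = 15, esd_alpha: float = 0.05) -> HemoTrace:
    """Apply the deviant-value and outlier rules to a hemodynamic trace.

    Samples flagged invalid upstream (no FWHM crossing, no detectable
    streak) are non-measurements: they are dropped first and counted in
    ``meta["n_missing"]``. Measured samples outside the physiological
    validity range for the trace kind (``DEFAULT_BOUNDS`` unless
    overridden) are replaced by the mean of the two nearest valid data
    points and flagged as replaced. For velocity and flux traces, a
    generalized ESD (Rosner's) test with up to ``esd_k_max`` outliers at
    ``esd_alpha`` then removes residual artifact values (radon
    misestimates on fast vessels); removals are recorded in
    ``meta["n_outliers_removed"]``. A trace with more than half its
    measured samples out of bounds is rejected.
    """
    lo, hi = DEFAULT_BOUNDS[t.kind] if bounds is None else bounds
    missing = ~np.isfinite(t.values) | (t.flags == FLAG_INVALID)
    n_missing = int(missing.sum())
    if n_missing == len(t.values):
        raise ValueError("all samples invalid; trace rejected")
    t = HemoTrace(kind=t.kind, times=t.times[~missing],
                  values=t.values[~missing], flags=t.flags[~missing],
                  meta={k: (v[~missing] if isinstance(v, np.ndarray)
                            and len(v) == len(missing) else v)
                        for k, v in t.meta.items()})
    vals = t.values.copy()
    bad = (vals < lo) | (vals > hi)
    if bad.mean() > 0.5:
        raise ValueError("more than 50% of samples out of bounds; trace rejected")
    flags = t.flags.copy()
    if bad.any():
        vals = _replace_deviant(vals, bad)
        flags[bad] = FLAG_REPLACED

    n_removed = 0
    times = t.times.copy()
    if t.kind in ("velocity", "flux"):
        out_idx = generalized_esd(vals, k_max=esd_k_max, alpha=esd_alpha)
        if len(out_idx):
            keep = np.ones(len(vals), dtype=bool)
            keep[out_idx] = False
            times, vals, flags = times[keep], vals[keep], flags[keep]
            n_removed = len(out_idx)
    meta = dict(t.meta)
    sep = meta.get("separability")
    if sep is not None and len(vals) != len(t.values):
        meta.pop("separability")
    meta["n_outliers_removed"] = n_removed
    meta["n_missing"] = n_missing
    return HemoTrace(kind=t.kind, times=times, values=vals, flags=flags,
                     meta=meta)


def resample_smooth(t: HemoTrace, target_rate: float = 10.0,
                    smooth_window_s: float = 1.0) -> HemoTrace:
    """Interpolate onto a uniform grid and apply moving-average smoothing.

    Linear interpolation onto ``target_rate`` samples/s over the trace
    span, then a centered moving average spanning ``smooth_window_s``
    (an odd number of samples — 11 at 10 samples/s — so the filter is
    symmetric); windows shrink at the endpoints.
    """
    ok = t.valid
    if ok.sum() < 2:
        raise ValueError("need at least 2 valid samples to resample")
    ts, vs = t.times[ok], t.values[ok]
    n_out = max(int(np.floor((ts[-1] - ts[0]) * target_rate)) + 1, 2)
    grid = ts[0] + np.arange(n_out) / target_rate
    interp = np.interp(grid, ts, vs)

    w = int(round(smooth_window_s * target_rate))
    w += (w + 1) % 2  # force odd for a symmetric window
    kernel = np.ones(w)
    num = np.convolve(interp, kernel, mode="same")
    den = np.convolve(np.ones(n_out), kernel, mode="same")
    smooth = num / den
    return HemoTrace(kind=t.kind, times=grid, values=smooth,
                     meta={**t.meta, "target_rate": target_rate,
                           "smooth_window_s": smooth_window_s})
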