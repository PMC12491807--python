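"""Synthetic two-photon data with recorded ground truth.

Every generator here emulates one class of raw data the analysis stages
consume — fluorescence movies with calcium transients, line-scan kymographs
encoding vessel width or moving blood cells, stimulus-locked trials, and
two-level grouped observation tables — and returns, next to the rendered
data, a :class:`GroundTruth` ledger of everything that was planted, so that
each analysis stage can be validated by parameter recovery.

Conventions
-----------
* time is axis 0 everywhere; kymograph lines are indexed from 0;
* positions are kept in pixels internally, converted through
  ``pixel_size`` (µm/px) only at reporting boundaries;
* times are seconds throughout (``line_period`` included);
* all randomness flows through one explicit :class:`numpy.random.Generator`
  (derived from ``SynthConfig.seed`` when not supplied), never global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .calcium import FluorescenceMovie, ROIMeta, ROISet
from .linescan import Kymograph
from .nvc import StimulusEpoch

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "NVCTrial",
    "gen_calcium_trace",
    "gen_calcium_movie",
    "gen_diameter_kymograph",
    "gen_velocity_kymograph",
    "gen_nvc_trial",
    "gen_grouped_observations",
    "default_roi_layout",
]


@dataclass(frozen=True)
class SynthConfig:
    """Shared acquisition parameters for the synthetic microscope.

    Defaults mirror a typical in-vivo two-photon session: 128×128-px
    frame scans at ~12 frames/s for 60-s trials, and line scans at ~2 ms
    per line with sub-micron pixels.

    Parameters
    ----------
    seed : int
        Seed for the generator used when no explicit RNG is passed.
    frame_rate : float
        Frame-scan rate, Hz.
    duration : float
        Trial length, s.
    image_size : (int, int)
        Frame size (y, x) in pixels.
    line_period : float
        Time per kymograph line, **seconds** (~0.0018–0.004 s typical).
    pixel_size : float
        Pixel pitch, µm/px.
    noise_sd : float
        Additive Gaussian noise SD, in the same intensity units as the
        rendered data.
    bleed_fraction : float
        Symmetric cross-channel bleed-through fraction in [0, 1).
    """

    seed: int = 0
    frame_rate: float = 12.0
    duration: float = 60.0
    image_size: tuple[int, int] = (128, 128)
    line_period: float = 0.002
    pixel_size: float = 0.5
    noise_sd: float = 0.0
    bleed_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.line_period <= 0:
            raise ValueError("line_period must be > 0")
        if not 0 <= self.bleed_fraction < 1:
            raise ValueError("bleed_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """Ledger of everything a generator planted.

    Only the fields relevant to the generating call are filled; the rest
    stay ``None``. Times are seconds from trial start, diameters µm,
    velocities mm/s.
    """

    event_times: Optional[np.ndarray] = None
    event_amplitudes: Optional[np.ndarray] = None
    roi_event_counts: Optional[dict] = None
    roi_events: Optional[dict] = None
    f0: Optional[float] = None
    base_diameter: Optional[float] = None
    vasomotion_freq: Optional[float] = None
    vasomotion_amp: Optional[float] = None
    diameter_times: Optional[np.ndarray] = None
    diameter_values: Optional[np.ndarray] = None
    velocity_times: Optional[np.ndarray] = None
    velocity_profile: Optional[np.ndarray] = None
    cell_entry_times: Optional[np.ndarray] = None
    flux_rate: Optional[float] = None
    stall_epochs: tuple = ()
    stimulus_epoch: Optional[StimulusEpoch] = None
    response_magnitudes: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def _event_kernel(t: np.ndarray, t0: float, amp: float, tau: float) -> np.ndarray:
    """Instant-rise, single-exponential-decay transient (dF/F units)."""
    out = np.zeros_like(t)
    m = t >= t0
    out[m] = amp * np.exp(-(t[m] - t0) / tau)
    return out


def gen_calcium_trace(
    cfg: SynthConfig,
    event_rate: float,
    amp_mean: float = 0.5,
    decay_tau: float = 1.0,
    oscillation: Optional[tuple[float, float]] = None,
    f0: float = 100.0,
    amp_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a raw fluorescence trace with Poisson calcium transients.

    The trace is ``f0 * (1 + Σ transients + oscillation) + noise`` where
    each transient has an instantaneous rise and exponential decay with
    time constant ``decay_tau`` (s) and amplitude in dF/F units drawn as
    ``Normal(amp_mean, amp_sd)``. ``oscillation`` is an optional
    ``(freq_hz, amplitude)`` sinusoid emulating slow vasomotion-coupled
    calcium rhythms. ``event_rate`` is in events per minute.
    """
    if event_rate < 0:
        raise ValueError("event_rate must be >= 0")
    if decay_tau <= 0:
        raise ValueError("decay_tau must be > 0")
    if f0 <= 0:
        raise ValueError("f0 must be > 0")
    rng = cfg.rng() if rng is None else rng
    n = int(round(cfg.duration * cfg.frame_rate))
    t = np.arange(n) / cfg.frame_rate

    n_ev = rng.poisson(event_rate / 60.0 * cfg.duration)
    times = np.sort(rng.uniform(0.0, cfg.duration, n_ev))
    amps = np.maximum(rng.normal(amp_mean, amp_sd, n_ev), 1e-3) if n_ev else np.empty(0)

    sig = np.zeros(n)
    for t0, a in zip(times, amps):
        sig += _event_kernel(t, t0, a, decay_tau)
    if oscillation is not None:
        fo, ao = oscillation
        sig = sig + ao * np.sin(2 * np.pi * fo * t)

    trace = f0 * (1.0 + sig)
    if cfg.noise_sd > 0:
        trace = trace + rng.normal(0.0, cfg.noise_sd, n)
    truth = GroundTruth(event_times=times, event_amplitudes=amps, f0=f0)
    return trace, truth


# ---------------------------------------------------------------------------
# movies


def default_roi_layout(image_size: tuple[int, int] = (128, 128)) -> ROISet:
    """A vessel-shaped mask with soma and process sub-regions.

    The vessel runs horizontally across the frame mid-height; ROI 1 is a
    soma disk sitting on the vessel, ROI 2 an elongated process strip
    along it.
    """
    ny, nx = image_size
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy = ny // 2
    vessel = np.abs(yy - cy) <= 6

    labels = np.zeros(image_size, dtype=np.int32)
    soma = (yy - cy) ** 2 + (xx - nx // 4) ** 2 <= 5**2
    process = (np.abs(yy - cy) <= 2) & (xx >= nx // 2) & (xx < nx - 10)
    labels[process & vessel] = 2
    labels[soma & vessel] = 1
    meta = {
        1: ROIMeta(compartment="soma", pericyte_id="p0",
                   pericyte_type="ensheathing", branch_order=1),
        2: ROIMeta(compartment="process", pericyte_id="p0",
                   pericyte_type="ensheathing", branch_order=1),
    }
    return ROISet(label_image=labels, meta=meta, vessel_mask=vessel)


def gen_calcium_movie(
    cfg: SynthConfig,
    roi_layout: Optional[ROISet] = None,
    events: Optional[dict[int, Sequence[tuple[float, float]]]] = None,
    event_rate: float = 0.0,
    amp_mean: float = 0.5,
    decay_tau: float = 1.0,
    blob_sigma: float = 2.5,
    f0_cell: float = 100.0,
    background: float = 10.0,
    plasma_level: float = 150.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[FluorescenceMovie, ROISet, GroundTruth]:
    """Render a two-channel movie: calcium on a vessel mask + labeled plasma.

    Channel 0 carries the calcium indicator: baseline ``f0_cell`` on the
    pericyte mask with transients rendered as spatial Gaussian blobs
    (``blob_sigma`` px) placed inside their ROI and decaying with
    ``decay_tau``. Channel 1 is the plasma label, uniform on the vessel
    mask. Cross-channel bleed of ``cfg.bleed_fraction`` is applied
    symmetrically; ``unmix_channels`` with the matching matrix inverts it
    exactly (up to clipping).

    ``events`` maps ROI label → list of ``(time_s, amplitude_dff)`` to
    plant explicitly; otherwise each ROI receives Poisson events at
    ``event_rate`` per minute.
    """
    rng = cfg.rng() if rng is None else rng
    rois = default_roi_layout(cfg.image_size) if roi_layout is None else roi_layout
    ny, nx = cfg.image_size
    if rois.label_image.shape != (ny, nx):
        raise ValueError("ROI layout does not match image size")
    nt = int(round(cfg.duration * cfg.frame_rate))
    t = np.arange(nt) / cfg.frame_rate

    cell_mask = rois.label_image > 0
    ca = np.where(cell_mask, f0_cell, background)[None, :, :] * np.ones((nt, 1, 1))
    plasma = np.where(rois.vessel_mask if rois.vessel_mask is not None else cell_mask,
                      plasma_level, background)[None, :, :] * np.ones((nt, 1, 1))

    yy, xx = np.mgrid[0:ny, 0:nx]
    roi_events: dict[int, list[tuple[float, float]]] = {}
    for label in rois.labels():
        if events is not None:
            ev = [(float(a), float(b)) for a, b in events.get(label, [])]
        else:
            n_ev = rng.poisson(event_rate / 60.0 * cfg.duration)
            ev = [(float(ti), float(max(rng.normal(amp_mean, 0.0), 1e-3)))
                  for ti in np.sort(rng.uniform(0, cfg.duration, n_ev))]
        roi_events[label] = ev
        pix = np.argwhere(rois.label_image == label)
        for t0, a in ev:
            if not 0 <= t0 <= cfg.duration:
                raise ValueError("event time outside trial")
            cy_, cx_ = pix[rng.integers(len(pix))]
            spatial = np.exp(-((yy - cy_) ** 2 + (xx - cx_) ** 2) / (2 * blob_sigma**2))
            spatial = spatial * cell_mask  # transients confined to the mask
            temporal = _event_kernel(t, t0, a * f0_cell, decay_tau)
            ca += temporal[:, None, None] * spatial[None, :, :]

    b = cfg.bleed_fraction
    obs0 = ca + b * plasma
    obs1 = plasma + b * ca
    data = np.stack([obs0, obs1], axis=-1)
    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd, data.shape)
    movie = FluorescenceMovie(
        data=np.ascontiguousarray(data, dtype=np.float32),
        frame_rate=cfg.frame_rate,
        channel_names=("calcium", "plasma"),
    )
    truth = GroundTruth(
        roi_events=roi_events,
        roi_event_counts={k: len(v) for k, v in roi_events.items()},
        f0=f0_cell,
    )
    return movie, rois, truth


# ---------------------------------------------------------------------------
# kymographs


def _stim_kernel(t: np.ndarray, stim: StimulusEpoch, ramp_s: float = 0.5) -> np.ndarray:
    """Smooth 0→1→0 plateau over the stimulus window (raised-cosine edges)."""
    k = np.zeros_like(t)
    on, off = stim.onset, stim.onset + stim.duration
    rise = (t >= on) & (t < on + ramp_s)
    k[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - on) / ramp_s))
    k[(t >= on + ramp_s) & (t <= off)] = 1.0
    fall = (t > off) & (t < off + ramp_s)
    k[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - off) / ramp_s))
    return k


def _coverage(x: np.ndarray, left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Fraction of the pixel cell [x-0.5, x+0.5] covered by [left, right].

    Area sampling keeps FWHM estimates exact for plateau profiles
    regardless of sub-pixel placement.
    """
    lo = np.maximum(x - 0.5, left)
    hi = np.minimum(x + 0.5, right)
    return np.clip(hi - lo, 0.0, 1.0)


def gen_diameter_kymograph(
    cfg: SynthConfig,
    d0: float = 10.0,
    vaso_amp: float = 0.0,
    vaso_freq: float = 0.1,
    edge_blur: float = 0.0,
    stim_response: Optional[tuple[StimulusEpoch, float]] = None,
    n_pos: int = 128,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    profile: str = "plateau",
    rng: Optional[np.random.Generator] = None,
) -> tuple[Kymograph, GroundTruth]:
    """Render a perpendicular line-scan of an oscillating vessel lumen.

    Each line is a bright plateau (or Gaussian, ``profile="gaussian"``) of
    width ``D(t) = d0·(1 + vaso_amp·sin(2π·vaso_freq·t))`` µm centered in
    the scan, edges optionally blurred by a Gaussian of ``edge_blur`` px.
    ``stim_response=(stim, frac)`` multiplies D(t) by a smooth
    stimulus-locked ``(1 + frac)`` plateau, emulating functional dilation.
    """
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    if not 0 <= vaso_amp < 1:
        raise ValueError("vaso_amp must be in [0, 1)")
    rng = cfg.rng() if rng is None else rng
    nlines = int(round(cfg.duration / cfg.line_period))
    t = np.arange(nlines) * cfg.line_period

    d_um = d0 * (1.0 + vaso_amp * np.sin(2 * np.pi * vaso_freq * t))
    stim = None
    if stim_response is not None:
        stim, frac = stim_response
        d_um = d_um * (1.0 + frac * _stim_kernel(t, stim))
    w_px = d_um / cfg.pixel_size
    if np.any(w_px >= n_pos - 4):
        raise ValueError("vessel width exceeds scan length")

    x = np.arange(n_pos, dtype=float)
    c = (n_pos - 1) / 2.0
    if profile == "plateau":
        data = _coverage(x[None, :], (c - w_px / 2)[:, None], (c + w_px / 2)[:, None])
    elif profile == "gaussian":
        sigma = w_px / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        data = np.exp(-((x[None, :] - c) ** 2) / (2 * sigma[:, None] ** 2))
    else:
        raise ValueError(f"unknown profile {profile!r}")
    data = baseline + amplitude * data
    if edge_blur > 0:
        data = gaussian_filter1d(data, edge_blur, axis=1, mode="nearest")
    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd, data.shape)

    kym = Kymograph(data=data, line_period=cfg.line_period,
                    pixel_size=cfg.pixel_size, orientation="perpendicular")
    truth = GroundTruth(
        base_diameter=d0, vasomotion_freq=vaso_freq, vasomotion_amp=vaso_amp,
        diameter_times=t, diameter_values=d_um, stimulus_epoch=stim,
        response_magnitudes=({"dilation": stim_response[1]} if stim_response else {}),
    )
    return kym, truth


def gen_velocity_kymograph(
    cfg: SynthConfig,
    velocity: float | np.ndarray,
    flux_rate: float,
    cell_width: float = 6.0,
    stall_epochs: Sequence[tuple[float, float]] = (),
    n_pos: int = 256,
    contrast: float = 0.4,
    plasma_level: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Kymograph, GroundTruth]:
    """Render a parallel line-scan: dark cell streaks on bright plasma.

    Blood cells arrive as a Poisson process at ``flux_rate`` cells/s,
    enter at one end of the scan and advance by ``v·line_period/pixel_size``
    px per line. Streaks are area-sampled dark bands of ``cell_width`` µm
    with multiplicative contrast (cell intensity ``1 − contrast`` of
    plasma); overlapping cells multiply, never going below zero. During
    ``stall_epochs`` the velocity is zero and streaks run parallel to the
    time axis.

    ``velocity`` may be a scalar (mm/s, nonzero, |v| ≤ 50) or an array of
    per-line velocities (mm/s) for time-varying flow.
    """
    if flux_rate < 0:
        raise ValueError("flux_rate must be >= 0")
    nlines = int(round(cfg.duration / cfg.line_period))
    t = np.arange(nlines) * cfg.line_period
    rng = cfg.rng() if rng is None else rng

    if np.isscalar(velocity):
        v = float(velocity)
        if v == 0.0:
            raise ValueError(
                "velocity 0 must be declared through stall_epochs, not the base velocity")
        if not 0 < abs(v) <= 50:
            raise ValueError("|velocity| must be in (0, 50] mm/s")
        v_line = np.full(nlines, v)
        for s0, s1 in stall_epochs:
            v_line[(t >= s0) & (t < s1)] = 0.0
    else:
        v_line = np.asarray(velocity, dtype=float)
        if v_line.shape != (nlines,):
            raise ValueError("per-line velocity array must have one value per line")

    px_per_line = v_line * 1e3 * cfg.line_period / cfg.pixel_size  # µm/ms ≡ mm/s
    disp = np.concatenate([[0.0], np.cumsum(px_per_line)])[:-1]  # px since t=0

    mean_speed = max(np.mean(np.abs(v_line)), 1e-6)
    transit = n_pos * cfg.pixel_size / (mean_speed * 1e3)
    n_main = rng.poisson(flux_rate * cfg.duration)
    entries = np.sort(rng.uniform(0.0, cfg.duration, n_main))
    n_pre = rng.poisson(flux_rate * transit)
    pre = np.sort(rng.uniform(-transit, 0.0, n_pre)) if n_pre else np.empty(0)

    forward = np.mean(v_line) >= 0
    w_half = cell_width / cfg.pixel_size / 2
    # entry fully off-screen so cells queued during a stall are invisible
    x_entry = -(w_half + 1) if forward else n_pos + w_half
    w_px = cell_width / cfg.pixel_size
    x = np.arange(n_pos, dtype=float)
    kym = np.full((nlines, n_pos), plasma_level)

    for t0 in np.concatenate([pre, entries]):
        i0 = int(np.clip(np.searchsorted(t, t0), 0, nlines - 1))
        disp0 = disp[i0] if t0 >= 0 else disp[0] + (t0 / cfg.line_period) * px_per_line[0]
        xc = x_entry + (disp - disp0)
        act = np.nonzero((xc > -w_px) & (xc < n_pos - 1 + w_px))[0]
        if len(act) == 0:
            continue
        if t0 >= 0:
            act = act[act >= i0]
            if len(act) == 0:
                continue
        cov = np.clip((w_px / 2 + 0.5) - np.abs(x[None, :] - xc[act, None]), 0.0, 1.0)
        kym[act] *= 1.0 - contrast * cov
    np.clip(kym, 0.0, None, out=kym)
    if cfg.noise_sd > 0:
        kym = kym + rng.normal(0.0, cfg.noise_sd, kym.shape)

    out = Kymograph(data=kym, line_period=cfg.line_period,
                    pixel_size=cfg.pixel_size, orientation="parallel")
    truth = GroundTruth(
        velocity_times=t, velocity_profile=v_line,
        cell_entry_times=entries, flux_rate=flux_rate,
        stall_epochs=tuple(stall_epochs),
        extras={"pre_entries": pre, "cell_width_um": cell_width},
    )
    return out, truth


# ---------------------------------------------------------------------------
# NVC trials


@dataclass
class NVCTrial:
    """One stimulus-locked trial: calcium trace + hemodynamic kymographs."""

    times_ca: np.ndarray
    ca_raw: np.ndarray
    diameter_kym: Kymograph
    velocity_kym: Optional[Kymograph]
    stim: StimulusEpoch
    truth: GroundTruth


def gen_nvc_trial(
    cfg: SynthConfig,
    stim: Optional[StimulusEpoch] = None,
    baseline_s: float = 5.0,
    ca_dip: float = 0.2,
    dilation: float = 0.1,
    velocity_gain: float = 0.2,
    d0: float = 10.0,
    v0: float = 2.0,
    f0: float = 100.0,
    flux_rate: float = 8.0,
    with_velocity: bool = True,
    kym_noise_sd: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> NVCTrial:
    """Render one functional-hyperemia trial.

    During the stimulus window (default a 5-s epoch after a 5-s
    pre-stimulus baseline, emulating 4-Hz whisker-pad stimulation) the
    calcium trace is depressed by ``ca_dip`` (fractional), the vessel
    diameter raised by ``dilation`` and the blood-cell velocity by
    ``velocity_gain``, each with smooth raised-cosine onset/offset. The
    programmed extrema are recorded in the ground truth.

    ``cfg.noise_sd`` applies to the calcium trace (intensity units on a
    baseline of ``f0``); the kymographs, whose profiles have unit
    amplitude, use ``kym_noise_sd``.
    """
    stim = StimulusEpoch(onset=baseline_s, duration=5.0,
                         description="500 uA at 4 Hz") if stim is None else stim
    if stim.onset < baseline_s:
        raise ValueError("stimulus onset must leave room for the pre-stimulus baseline")
    rng = cfg.rng() if rng is None else rng

    n = int(round(cfg.duration * cfg.frame_rate))
    t_ca = np.arange(n) / cfg.frame_rate
    ca = f0 * (1.0 - ca_dip * _stim_kernel(t_ca, stim))
    if cfg.noise_sd > 0:
        ca = ca + rng.normal(0.0, cfg.noise_sd, n)

    kcfg = cfg.with_(noise_sd=kym_noise_sd)
    diam_kym, _ = gen_diameter_kymograph(
        kcfg, d0=d0, vaso_amp=0.0, stim_response=(stim, dilation), rng=rng)

    vel_kym = None
    if with_velocity:
        nlines = int(round(cfg.duration / cfg.line_period))
        tl = np.arange(nlines) * cfg.line_period
        v_line = v0 * (1.0 + velocity_gain * _stim_kernel(tl, stim))
        vel_kym, _ = gen_velocity_kymograph(kcfg, v_line, flux_rate, rng=rng)

    truth = GroundTruth(
        stimulus_epoch=stim, f0=f0, base_diameter=d0,
        response_magnitudes={"ca_dip": ca_dip, "dilation": dilation,
                             "velocity_gain": velocity_gain},
        extras={"v0": v0},
    )
    return NVCTrial(times_ca=t_ca, ca_raw=ca, diameter_kym=diam_kym,
                    velocity_kym=vel_kym, stim=stim, truth=truth)


# ---------------------------------------------------------------------------
# grouped observations


def gen_grouped_observations(
    n_animals: int = 7,
    units_per_animal: int = 6,
    trials_per_unit: int = 2,
    treatment_effect: float = 0.0,
    sd_animal: float = 0.5,
    sd_unit: float = 0.5,
    sd_resid: float = 1.0,
    mu: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a paired pre/post cohort with animal and unit random effects.

    ``y = µ + δ·[post] + a_animal + b_unit + ε`` with Gaussian components;
    the same units are measured in both conditions (paired design), with
    ``trials_per_unit`` repeats per condition. Returns a long-format table
    with columns (animal_id, unit_id, compartment, branch_order,
    treatment, trial, value) ready for the mixed-model layer.
    """
    if n_animals < 2:
        raise ValueError("need at least 2 animals")
    if min(sd_animal, sd_unit, sd_resid) < 0:
        raise ValueError("all SDs must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows = []
    for a in range(n_animals):
        a_eff = rng.normal(0.0, sd_animal)
        for u in range(units_per_animal):
            u_eff = rng.normal(0.0, sd_unit)
            for cond in ("pre", "post"):
                delta = treatment_effect if cond == "post" else 0.0
                for tr in range(trials_per_unit):
                    y = mu + delta + a_eff + u_eff + rng.normal(0.0, sd_resid)
                    rows.append((f"a{a}", f"a{a}_u{u}", "soma", 1 + u % 3,
                                 cond, tr, y))
    table = pd.DataFrame(rows, columns=[
        "animal_id", "unit_id", "compartment", "branch_order",
        "treatment", "trial", "value"])
    truth = GroundTruth(extras={
        "delta": treatment_effect, "mu": mu,
        "sd_animal": sd_animal, "sd_unit": sd_unit, "sd_resid": sd_resid})
    return table, truth
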