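"""Pericyte calcium signal extraction from two-channel movies.

The stages mirror a standard in-vivo two-photon workflow: spectral
unmixing of indicator/plasma channels, ROI trace extraction, dF/F₀
against a trial-start baseline, band-passed peak detection, 3-D
(x, y, t) event detection at a baseline-SD threshold, and the power
spectral density of slow calcium rhythms in the vasomotion band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "FluorescenceMovie",
    "ROIMeta",
    "ROISet",
    "CalciumTrace",
    "CalciumEvent",
    "SpectralSummary",
    "unmix_channels",
    "extract_roi_trace",
    "compute_dff",
    "compute_f0_basal",
    "detect_peaks",
    "detect_events_3d",
    "compute_psd_peak",
]


@dataclass
class FluorescenceMovie:
    """Intensity stack ``(time, y, x[, channel])`` with a frame rate in Hz."""

    data: np.ndarray
    frame_rate: float
    channel_names: tuple[str, ...] = ("calcium",)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError("movie data must be (t, y, x) or (t, y, x, c)")
        if not 0 < self.frame_rate <= 1000:
            raise ValueError("frame_rate must be in (0, 1000] Hz")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names must match the channel count")

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[-1]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def channel(self, i: int) -> np.ndarray:
        return self.data if self.data.ndim == 3 else self.data[..., i]


@dataclass(frozen=True)
class ROIMeta:
    compartment: str  # "soma" | "process"
    pericyte_id: str = "p0"
    pericyte_type: str = "ensheathing"  # or "thin-strand"
    branch_order: int = 1


@dataclass
class ROISet:
    """Labeled ROI image plus per-ROI metadata.

    ``label_image`` holds positive integer labels (0 = background);
    ``vessel_mask`` optionally marks the vessel structure used to confirm
    that detected events lie on the cell/vessel and not in neuropil.
    """

    label_image: np.ndarray
    meta: dict[int, ROIMeta] = field(default_factory=dict)
    vessel_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.min() < 0:
            raise ValueError("ROI labels must be non-negative")
        for lbl in self.labels():
            if not np.any(self.label_image == lbl):
                raise ValueError(f"ROI {lbl} is empty")

    def labels(self) -> list[int]:
        found = {int(v) for v in np.unique(self.label_image)} - {0}
        return sorted(found | {int(k) for k in self.meta})

    def mask(self, label: int) -> np.ndarray:
        m = self.label_image == label
        if not m.any():
            raise ValueError(f"ROI {label} is empty")
        return m


@dataclass
class CalciumTrace:
    """dF/F₀ series with its baseline F₀ and sampling rate."""

    dff: np.ndarray
    f0: float
    sampling_rate: float
    roi_ref: Optional[int] = None

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        self.dff = np.asarray(self.dff, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.dff)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.dff) / self.sampling_rate


@dataclass(frozen=True)
class CalciumEvent:
    time: float  # s
    amplitude: float  # dF/F
    duration: float  # s
    roi_ref: Optional[int] = None
    source: str = "peak"  # "peak" | "event3d"


@dataclass
class SpectralSummary:
    freqs: np.ndarray
    psd: np.ndarray
    amplitude: np.ndarray
    peak_freq: float
    band: tuple[float, float]


# ---------------------------------------------------------------------------


def unmix_channels(movie: FluorescenceMovie, matrix: np.ndarray) -> FluorescenceMovie:
    """Invert a 2×2 linear mixing of the two channels, per pixel.

    ``matrix`` maps clean → observed intensities; the observed vector at
    each pixel is multiplied by its inverse. Negative results are clipped
    at zero (photon counts cannot be negative).
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape != (2, 2):
        raise ValueError("mixing matrix must be 2x2")
    if movie.n_channels != 2:
        raise ValueError("unmixing requires a 2-channel movie")
    if abs(np.linalg.det(m)) < 1e-12:
        raise np.linalg.LinAlgError("singular mixing matrix")
    inv = np.linalg.inv(m)
    out = np.einsum("tyxc,dc->tyxd", np.asarray(movie.data, dtype=float), inv)
    np.clip(out, 0.0, None, out=out)
    return FluorescenceMovie(data=out.astype(movie.data.dtype, copy=False),
                             frame_rate=movie.frame_rate,
                             channel_names=movie.channel_names)


def extract_roi_trace(movie: FluorescenceMovie, roi: np.ndarray | int,
                      rois: Optional[ROISet] = None, channel: int = 0) -> np.ndarray:
    """Per-frame mean intensity over the ROI pixels.

    ``roi`` is either a boolean mask or an ROI label (with ``rois`` given).
    """
    if isinstance(roi, (int, np.integer)):
        if rois is None:
            raise ValueError("ROI label given without an ROISet")
        mask = rois.mask(int(roi))
    else:
        mask = np.asarray(roi, dtype=bool)
    if mask.shape != movie.data.shape[1:3]:
        raise ValueError("ROI mask does not match the image size")
    if not mask.any():
        raise ValueError("empty ROI")
    return movie.channel(channel)[:, mask].mean(axis=1)


def compute_dff(raw: np.ndarray, sampling_rate: float,
                baseline_window_s: float = 5.0,
                roi_ref: Optional[int] = None) -> CalciumTrace:
    """dF/F₀ with F₀ = mean of the first ``baseline_window_s`` seconds."""
    raw = np.asarray(raw, dtype=float)
    nb = int(round(baseline_window_s * sampling_rate))
    if len(raw) <= nb:
        raise ValueError("trace shorter than the baseline window")
    f0 = float(raw[:nb].mean())
    if f0 <= 0:
        raise ValueError("non-positive baseline F0; trace flagged, not silently NaN")
    return CalciumTrace(dff=(raw - f0) / f0, f0=f0,
                        sampling_rate=sampling_rate, roi_ref=roi_ref)


def compute_f0_basal(source, sampling_rate: Optional[float] = None,
                     rois: Optional[ROISet] = None,
                     window_s: float = 2.5):
    """Basal fluorescence: mean over the first ``window_s`` seconds.

    Given a 1-D trace (with ``sampling_rate``) returns a scalar; given a
    movie and an ROISet returns ``{label: F0}``.
    """
    if isinstance(source, FluorescenceMovie):
        nb = int(round(window_s * source.frame_rate))
        if source.n_frames < nb:
            raise ValueError("movie shorter than the basal window")
        if rois is None:
            return float(source.channel(0)[:nb].mean())
        return {lbl: float(extract_roi_trace(source, lbl, rois)[:nb].mean())
                for lbl in rois.labels()}
    trace = np.asarray(source, dtype=float)
    if sampling_rate is None:
        raise ValueError("sampling_rate required for trace input")
    nb = int(round(window_s * sampling_rate))
    if len(trace) < nb:
        raise ValueError("trace shorter than the basal window")
    return float(trace[:nb].mean())


_SD_FLOOR_FRAC = 1e-6  # relative SD floor for noise-free inputs


def detect_peaks(ca: CalciumTrace,
                 band_hz: tuple[float, float] = (0.01, 2.0),
                 prominence_sd: float = 3.5,
                 min_separation_s: float = 1.0,
                 ) -> tuple[list[CalciumEvent], dict]:
    """Band-pass the dF/F trace and detect transients above a SD-scaled
    prominence.

    The prominence threshold is ``prominence_sd`` times a robust
    (MAD-based) SD of the *filtered* trace — robust so that the
    transients themselves do not inflate the noise estimate, and taken
    over the whole trace so the estimate does not hinge on whether the
    trial-start window happens to contain an event. Amplitudes are read
    from the unfiltered dF/F near the peak (filtering is for detection
    only). Two candidate peaks closer than ``min_separation_s`` are
    counted once (the higher wins — scipy's ``distance`` rule).

    Returns the event list and a summary with ``events_per_min`` and
    ``amp_mean``.
    """
    lo, hi = band_hz
    nyq = ca.sampling_rate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=ca.sampling_rate,
                        output="sos")
    filt = signal.sosfiltfilt(sos, ca.dff)

    sd = 1.4826 * float(np.median(np.abs(filt - np.median(filt))))
    sd = max(sd, _SD_FLOOR_FRAC * max(abs(float(np.mean(ca.dff))), 1.0))

    dist = max(int(round(min_separation_s * ca.sampling_rate)), 1)
    idx, props = signal.find_peaks(filt, prominence=prominence_sd * sd,
                                   distance=dist)
    widths = signal.peak_widths(filt, idx, rel_height=0.5)[0] / ca.sampling_rate
    halfwin = max(int(round(0.25 * ca.sampling_rate)), 1)
    events = []
    for i, w in zip(idx, widths):
        amp = float(ca.dff[max(i - halfwin, 0):i + halfwin + 1].max())
        events.append(CalciumEvent(time=float(i / ca.sampling_rate),
                                   amplitude=amp, duration=float(w),
                                   roi_ref=ca.roi_ref, source="peak"))
    events = [e for e in events if e.amplitude > 0]
    summary = {
        "events_per_min": len(events) / ca.duration * 60.0,
        "amp_mean": float(np.mean([e.amplitude for e in events])) if events else 0.0,
    }
    return events, summary


def detect_events_3d(movie: FluorescenceMovie, rois: ROISet,
                     k: float = 3.0, min_size: int = 4, min_duration: int = 2,
                     baseline_s: float = 5.0,
                     ) -> tuple[dict[int, float], list[CalciumEvent]]:
    """Threshold-based spatiotemporal event detection.

    Per-pixel baseline mean and SD come from the first ``baseline_s``
    seconds; voxels exceeding ``mean + k·SD`` are grouped into
    26-connected components over (x, y, t). Components are kept if they
    touch the vessel structure (``rois.vessel_mask`` when present,
    otherwise any ROI), span at least ``min_duration`` frames and
    ``min_size`` voxels. The per-ROI frequency is the number of retained
    components intersecting that ROI, per minute.

    A relative SD floor stands in for zero baseline SD on noise-free
    input, so the threshold rule stays well-defined instead of raising.
    """
    if movie.n_channels != 1:
        raise ValueError("detect_events_3d expects a single (unmixed) calcium channel")
    data = np.asarray(movie.channel(0), dtype=float)
    nb = max(int(round(baseline_s * movie.frame_rate)), 2)
    base_mean = data[:nb].mean(axis=0)
    base_sd = data[:nb].std(axis=0)
    floor = _SD_FLOOR_FRAC * np.maximum(np.abs(base_mean), 1.0)
    base_sd = np.maximum(base_sd, floor)

    active = data > (base_mean + k * base_sd)[None]
    labels, n_comp = ndimage.label(active, structure=np.ones((3, 3, 3), dtype=bool))

    vessel = rois.vessel_mask if rois.vessel_mask is not None else rois.label_image > 0
    events: list[CalciumEvent] = []
    counts = {lbl: 0 for lbl in rois.labels()}
    if n_comp:
        objects = ndimage.find_objects(labels)
        for ci, sl in enumerate(objects, start=1):
            comp = labels[sl] == ci
            if comp.sum() < min_size:
                continue
            t_extent = sl[0].stop - sl[0].start
            if t_extent < min_duration:
                continue
            footprint = comp.any(axis=0)  # spatial support within the slice
            sub_vessel = vessel[sl[1], sl[2]]
            if not np.any(footprint & sub_vessel):
                continue  # outside the vessel structure: rejected
            # peak voxel time for the event timestamp
            vals = np.where(comp, data[sl], -np.inf)
            t_peak = sl[0].start + int(np.unravel_index(np.argmax(vals), vals.shape)[0])
            amp = float(vals.max())
            hit_any = False
            for lbl in counts:
                sub_roi = (rois.label_image == lbl)[sl[1], sl[2]]
                if np.any(footprint & sub_roi):
                    counts[lbl] += 1
                    events.append(CalciumEvent(
                        time=t_peak / movie.frame_rate, amplitude=amp,
                        duration=t_extent / movie.frame_rate,
                        roi_ref=lbl, source="event3d"))
                    hit_any = True
            if not hit_any:
                events.append(CalciumEvent(
                    time=t_peak / movie.frame_rate, amplitude=amp,
                    duration=t_extent / movie.frame_rate,
                    roi_ref=None, source="event3d"))
    per_min = {lbl: c / movie.duration * 60.0 for lbl, c in counts.items()}
    return per_min, events


def compute_psd_peak(ca, sampling_rate: Optional[float] = None,
                     band: tuple[float, float] = (0.01, 0.5)) -> SpectralSummary:
    """Periodogram of the mean-removed trace and its peak in ``band``.

    Uses a plain boxcar periodogram of the full trace (no Welch
    averaging) so the lowest band edge remains resolvable on 60-s trials.
    ``ca`` may be a :class:`CalciumTrace` or a plain array with
    ``sampling_rate``.
    """
    if isinstance(ca, CalciumTrace):
        x, fs = ca.dff, ca.sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for array input")
        x, fs = np.asarray(ca, dtype=float), float(sampling_rate)
    x = x - x.mean()
    freqs, psd = signal.periodogram(x, fs=fs, window="boxcar", detrend=False)
    n = len(x)
    # single-sided amplitude spectrum, per the usual |FFT|/N doubling
    amp_full = np.abs(np.fft.rfft(x)) / n
    amplitude = amp_full.copy()
    amplitude[1:] *= 2.0
    if n % 2 == 0 and len(amplitude) > 1:
        amplitude[-1] /= 2.0

    lo, hi = band
    in_band = (freqs >= lo) & (freqs <= hi) & (freqs > 0)
    if in_band.sum() < 2:
        raise ValueError("frequency band unresolvable at this trace duration")
    band_freqs = freqs[in_band]
    peak = float(band_freqs[np.argmax(psd[in_band])])
    return SpectralSummary(freqs=freqs, psd=psd, amplitude=amplitude,
                           peak_freq=peak, band=band)
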