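"""Stimulus-locked neurovascular-coupling (NVC) analysis.

Converts calcium and hemodynamic series into percentage change relative
to a pre-stimulus baseline and extracts the stimulus-window extremum:
the minimum for calcium (pericytes transiently drop Ca²⁺ during
functional hyperemia) and the maximum for diameter, velocity and flux.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StimulusEpoch",
    "NVCResponse",
    "pct_change_trace",
    "response_extrema",
    "analyze_nvc",
    "average_trials",
]


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulation window: onset and duration in seconds.

    The canonical protocol is a 5-s, 4-Hz, 500-µA whisker-pad stimulus
    delivered after a 5-s pre-stimulus baseline.
    """

    onset: float
    duration: float
    description: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        if self.onset < 0:
            raise ValueError("stimulus onset must be >= 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class NVCResponse:
    """Percent-change trace plus its stimulus-window extremum."""

    times: np.ndarray
    pct_trace: np.ndarray
    stim: StimulusEpoch
    baseline_value: float
    extremum_pct: float
    mode: str  # "min" | "max"
    baseline_window_s: float = 5.0


def pct_change_trace(times: np.ndarray, values: np.ndarray,
                     stim: StimulusEpoch, baseline_s: float = 5.0
                     ) -> tuple[np.ndarray, float]:
    """Percent change relative to the pre-stimulus baseline.

    The baseline is the mean over the ``baseline_s`` window immediately
    before stimulus onset; the trace must cover the full baseline and
    stimulus windows. Returns ``(pct, baseline)`` with
    ``pct = 100·(x − baseline)/baseline``.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    if times[0] > stim.onset - baseline_s + dt or times[-1] < stim.offset - dt:
        raise ValueError("series does not cover the baseline + stimulus windows")
    in_base = (times >= stim.onset - baseline_s) & (times < stim.onset)
    if not in_base.any():
        raise ValueError("empty pre-stimulus baseline window")
    baseline = float(values[in_base].mean())
    if baseline <= 0:
        raise ValueError("non-positive pre-stimulus baseline")
    return 100.0 * (values - baseline) / baseline, baseline


def response_extrema(times: np.ndarray, pct: np.ndarray,
                     stim: StimulusEpoch, mode: str) -> float:
    """Extremum of the percent-change trace strictly within the stimulus
    window (``min`` for calcium, ``max`` for hemodynamics)."""
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    times = np.asarray(times, dtype=float)
    in_win = (times >= stim.onset) & (times <= stim.offset)
    if not in_win.any():
        raise ValueError("no samples inside the stimulus window")
    seg = np.asarray(pct, dtype=float)[in_win]
    return float(seg.min() if mode == "min" else seg.max())


def analyze_nvc(times: np.ndarray, values: np.ndarray, stim: StimulusEpoch,
                mode: str, baseline_s: float = 5.0) -> NVCResponse:
    """Percent-change trace and stimulus-window extremum in one step."""
    pct, base = pct_change_trace(times, values, stim, baseline_s)
    ext = response_extrema(times, pct, stim, mode)
    return NVCResponse(times=times, pct_trace=pct, stim=stim,
                       baseline_value=base, extremum_pct=ext, mode=mode,
                       baseline_window_s=baseline_s)


def average_trials(pct_traces: Sequence[np.ndarray]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Mean ± SEM across repeated stimulation trials on a common grid."""
    arr = np.asarray(list(pct_traces), dtype=float)
    if arr.ndim != 2:
        raise ValueError("trials must share one time grid")
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 \
        else np.zeros_like(mean)
    return mean, sem
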