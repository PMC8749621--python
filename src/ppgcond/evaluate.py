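"""Post-filtering, peak detection and sliding-window heart-rate scoring.

The conditioned PPG is band-passed with a zero-phase Butterworth filter
(applied forwards and backwards so peak positions are preserved), peaks
are detected with a refractory-constrained local-maximum detector, the
peak train is converted to beats per minute inside sliding windows
(8 s length, 2 s shift by default), and accuracy is reported as the
mean absolute error in bpm against the ground-truth peak train.

The peak detector here is a deliberately simple, parameterised
stand-in: local maxima above a fraction of a running amplitude
envelope, separated by at least a refractory interval (0.25 s default,
a 240 bpm ceiling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

from .signal_core import PeakAnnotation

__all__ = [
    "HREvaluation",
    "zero_phase_bandpass",
    "butter_sos",
    "detect_peaks",
    "hr_in_window",
    "evaluate_mae",
    "aggregate",
]

DEFAULT_BAND = (0.5, 4.0)  # Hz; 30-240 bpm
DEFAULT_ORDER = 8
DEFAULT_WINDOW = 8.0  # s
DEFAULT_SHIFT = 2.0  # s


@dataclass
class HREvaluation:
    """Sliding-window heart-rate comparison for one record."""

    window_length: float
    shift: float
    per_window: list[tuple[float, float | None, float | None]]
    mae: float | None
    n_windows: int
    n_undefined: int


def butter_sos(
    sampling_rate: float,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Butterworth bandpass of the given overall order in SOS form."""
    if not 0 < low_hz < high_hz < sampling_rate / 2:
        raise ValueError("band must satisfy 0 < low < high < Nyquist")
    if order % 2:
        raise ValueError("overall bandpass order must be even")
    return sps.butter(
        order // 2, [low_hz, high_hz], btype="bandpass", fs=sampling_rate,
        output="sos",
    )


def zero_phase_bandpass(
    x: np.ndarray,
    sampling_rate: float,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Forward-backward Butterworth bandpass (zero phase distortion).

    The two passes square the magnitude response while cancelling the
    phase, so symmetric features keep their sample positions.
    """
    sos = butter_sos(sampling_rate, low_hz, high_hz, order)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def detect_peaks(
    x: np.ndarray,
    sampling_rate: float,
    refractory: float = 0.25,
    rel_threshold: float = 0.3,
    envelope_window: float = 2.0,
) -> PeakAnnotation:
    """Refractory-constrained local-maximum peak detector.

    Local maxima separated by at least ``refractory`` seconds (the
    larger of two close maxima wins) are kept when they exceed
    ``rel_threshold`` times a running amplitude envelope (moving maximum
    of |x| over ``envelope_window`` seconds).  Peak times are at sample
    resolution; an empty result is legal.
    """
    x = np.asarray(x, dtype=float)
    distance = max(1, int(round(refractory * sampling_rate)))
    idx, _ = sps.find_peaks(x, distance=distance)
    if len(idx) == 0:
        return PeakAnnotation(np.empty(0))
    win = max(1, int(round(envelope_window * sampling_rate)))
    envelope = ndimage.maximum_filter1d(np.abs(x), size=win, mode="nearest")
    keep = x[idx] >= rel_threshold * envelope[idx]
    return PeakAnnotation(idx[keep] / sampling_rate)


def hr_in_window(
    peaks: PeakAnnotation,
    t0: float,
    t1: float,
    method: str = "mean",
) -> float | None:
    """Heart rate in bpm from the peaks inside [t0, t1).

    60 / (mean inter-peak interval); ``method="median"`` swaps in the
    median interval.  Returns None with fewer than two peaks.
    """
    if not t1 > t0:
        raise ValueError("t1 must exceed t0")
    inside = peaks.peak_times[(peaks.peak_times >= t0) & (peaks.peak_times < t1)]
    if len(inside) < 2:
        return None
    intervals = np.diff(inside)
    period = float(np.median(intervals) if method == "median" else np.mean(intervals))
    return 60.0 / period


def evaluate_mae(
    est: PeakAnnotation,
    truth: PeakAnnotation,
    duration: float,
    window_length: float = DEFAULT_WINDOW,
    shift: float = DEFAULT_SHIFT,
    method: str = "mean",
) -> HREvaluation:
    """Sliding-window MAE in bpm between two peak trains.

    Windows start at 0, shift, 2*shift, ... while the window still fits
    in the record; windows where either train defines no rate are
    excluded (their count is reported).
    """
    starts = []
    t0 = 0.0
    while t0 + window_length <= duration + 1e-9:
        starts.append(t0)
        t0 += shift
    per_window = []
    errors = []
    undefined = 0
    for t0 in starts:
        e = hr_in_window(est, t0, t0 + window_length, method)
        g = hr_in_window(truth, t0, t0 + window_length, method)
        per_window.append((t0, e, g))
        if e is None or g is None:
            undefined += 1
        else:
            errors.append(abs(e - g))
    if not errors:
        warnings.warn("no window defines a heart rate in both trains")
        mae = None
    else:
        mae = float(np.mean(errors))
    return HREvaluation(
        window_length=window_length,
        shift=shift,
        per_window=per_window,
        mae=mae,
        n_windows=len(starts),
        n_undefined=undefined,
    )


def aggregate(evaluations: list[HREvaluation]) -> tuple[float, float]:
    """Corpus-level mean and standard deviation of per-record MAEs."""
    maes = [e.mae for e in evaluations if e.mae is not None]
    if not maes:
        raise ValueError("no defined MAE to aggregate")
    return float(np.mean(maes)), float(np.std(maes))
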