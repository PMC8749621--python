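"""Reference (target) PPG synthesis from peak annotations.

A captured record has reliable peak detections only inside the two
movement-free windows (Time Window A at the head, Time Window B at the
tail).  The reference waveform is built in four steps:

1. ``window_periods`` — take the last inter-peak interval of Window A
   (``T_A``), the first of Window B (``T_B``) and their mean ``T_M``.
2. ``check_gap`` — count how many beats fit in the gap between the last
   A-peak ``t_A`` and the last B-peak ``t_B``: ``n = (t_B - t_A) / T_M``,
   rounded half-up to ``n_round``; the annotation is usable when the
   rounding deviation |n - n_round| stays within ``max_dev``.
3. ``interpolate_intervals`` — fill the gap with ``n_round`` intervals
   that ramp linearly from ~``T_A`` to ~``T_B`` and sum exactly to
   ``t_B - t_A``, inserting ``n_round - 1`` interior peaks.
4. ``synthesize_target`` — lay a piecewise cosine with a maximum at
   every peak (one full period per beat), flatten the negative lobe by a
   factor ``G`` (PPG pulses are bottom-flattened), and min-max normalize
   to [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_core import PeakAnnotation, SignalRecord

__all__ = [
    "GapInterpolation",
    "ReferenceResult",
    "window_periods",
    "check_gap",
    "interpolate_intervals",
    "synthesize_target",
    "bottom_flatten",
    "build_reference",
    "DEFAULT_G",
]

DEFAULT_G = 0.3


@dataclass
class GapInterpolation:
    """Bookkeeping of one gap interpolation (all times in seconds)."""

    T_A: float
    T_B: float
    T_M: float
    t_A: float
    t_B: float
    n: float
    n_round: int
    valid: bool
    intervals: np.ndarray
    inserted_peaks: np.ndarray


@dataclass
class ReferenceResult:
    """Outcome of ``build_reference``: the (possibly) targeted record,
    the gap bookkeeping, and whether the annotation was rejected."""

    record: SignalRecord
    gap: GapInterpolation
    rejected: bool


def window_periods(annotation: PeakAnnotation) -> tuple[float, float, float]:
    """Inter-peak periods anchoring the gap interpolation.

    Returns ``(T_A, T_B, T_M)``: the difference of the last two peaks of
    Window A, the difference of the first two peaks of Window B, and
    their arithmetic mean.
    """
    if annotation.window_a_end is None:
        raise ValueError("annotation has no clean-window boundaries")
    peaks_a = annotation.peaks_before(annotation.window_a_end)
    peaks_b = annotation.peaks_after(annotation.window_b_start)
    if len(peaks_a) < 2:
        raise ValueError("need >= 2 peaks inside Time Window A")
    if len(peaks_b) < 2:
        raise ValueError("need >= 2 peaks inside Time Window B")
    T_A = float(peaks_a[-1] - peaks_a[-2])
    T_B = float(peaks_b[1] - peaks_b[0])
    return T_A, T_B, 0.5 * (T_A + T_B)


def check_gap(t_A: float, t_B: float, T_M: float) -> tuple[float, int, bool]:
    """Beat count across the gap and its rounding validity.

    ``n = (t_B - t_A)/T_M``; ``n_round`` is n rounded half-up; the gap is
    valid when ``|n - n_round| <= 0.5`` (the boundary counts as valid).
    """
    if not T_M > 0:
        raise ValueError("T_M must be positive")
    if not t_B > t_A:
        raise ValueError("t_B must exceed t_A")
    n = (t_B - t_A) / T_M
    n_round = int(math.floor(n + 0.5))  # round half-up
    valid = abs(n - n_round) <= 0.5
    return n, n_round, valid


def interpolate_intervals(
    T_A: float, t_A: float, t_B: float, n_round: int
) -> np.ndarray:
    """Linearly ramped inter-peak intervals filling the gap.

    ``T_i = T_A + 2 i ((t_B - t_A)/n_round - T_A) / (n_round + 1)`` for
    i = 1..n_round.  The intervals are linear in i and sum exactly to
    ``t_B - t_A`` (algebraic identity), so cumulative sums from ``t_A``
    insert ``n_round - 1`` interior peaks and land on ``t_B``.
    """
    if n_round < 1:
        raise ValueError("n_round must be >= 1")
    i = np.arange(1, n_round + 1, dtype=float)
    return T_A + 2.0 * i * ((t_B - t_A) / n_round - T_A) / (n_round + 1)


def bottom_flatten(s: np.ndarray | float, G: float = DEFAULT_G):
    """Compress the negative lobe: s for s >= 0, G*s for s < 0.

    Continuous and monotone at 0 for any G in (0, 1]; mimics the
    bottom-flattened shape of a real PPG pulse.
    """
    s = np.asarray(s, dtype=float)
    out = np.where(s >= 0.0, s, G * s)
    return out if out.ndim else float(out)


def synthesize_target(
    peaks: np.ndarray,
    length: int,
    sampling_rate: float,
    G: float = DEFAULT_G,
) -> np.ndarray:
    """Idealised PPG through the given peak times.

    Piecewise cosine with value +1 at every peak and one full period per
    consecutive peak pair; before the first / after the last peak the
    adjacent segment's period is extended.  The negative lobe is
    compressed by ``G`` and the result min-max normalized to [-1, 1].
    """
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) < 2:
        raise ValueError("need >= 2 peaks to synthesize a target")
    t = np.arange(length) / sampling_rate
    # segment index for each sample: peaks[k] <= t < peaks[k+1]
    k = np.clip(np.searchsorted(peaks, t, side="right") - 1, 0, len(peaks) - 2)
    periods = np.diff(peaks)
    phase = (t - peaks[k]) / periods[k]  # extends linearly outside [0, 1)
    s = np.cos(2.0 * np.pi * phase)
    s = bottom_flatten(s, G)
    lo, hi = s.min(), s.max()
    if hi == lo:
        return np.zeros(length)
    return 2.0 * (s - lo) / (hi - lo) - 1.0


def build_reference(
    record: SignalRecord,
    annotation: PeakAnnotation,
    G: float = DEFAULT_G,
    max_dev: float = 0.5,
) -> ReferenceResult:
    """Attach the reference target waveform to a record.

    Composes ``window_periods`` → ``check_gap`` → ``interpolate_intervals``
    → ``synthesize_target``.  Peaks of Window A are kept as annotated;
    the interior of the record up to the last Window-B peak is replaced
    by the interpolated peak train.  If the gap fails the rounding check
    (deviation > ``max_dev``), the record is flagged rejected and
    returned without a target.
    """
    T_A, T_B, T_M = window_periods(annotation)
    peaks_a = annotation.peaks_before(annotation.window_a_end)
    peaks_b = annotation.peaks_after(annotation.window_b_start)
    t_A, t_B = float(peaks_a[-1]), float(peaks_b[-1])
    n, n_round, _ = check_gap(t_A, t_B, T_M)
    valid = abs(n - n_round) <= max_dev
    if not valid:
        gap = GapInterpolation(
            T_A, T_B, T_M, t_A, t_B, n, n_round, False,
            np.empty(0), np.empty(0),
        )
        return ReferenceResult(record, gap, rejected=True)
    intervals = interpolate_intervals(T_A, t_A, t_B, n_round)
    filled = t_A + np.cumsum(intervals)
    inserted = filled[:-1]  # n_round - 1 interior peaks; filled[-1] == t_B
    all_peaks = np.concatenate([peaks_a, filled])
    target = synthesize_target(all_peaks, len(record), record.sampling_rate, G)
    gap = GapInterpolation(
        T_A, T_B, T_M, t_A, t_B, n, n_round, True, intervals, inserted
    )
    return ReferenceResult(record.replace(target=target), gap, rejected=False)
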