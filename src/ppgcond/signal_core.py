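"""Domain types and file I/O for multichannel wrist-sensor records.

A record couples one photoplethysmography (PPG) channel with the three
axes of an accelerometer, all uniformly sampled (32 Hz by default, the
rate of the capture protocol: ~1024 samples over ~32 s).  An optional
``target`` channel holds the idealised reference PPG used for supervised
training.  Peak annotations carry the ground-truth (or detected) systolic
peak times together with the boundaries of the two movement-free windows
at the head and tail of a record.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SignalRecord",
    "PeakAnnotation",
    "FormatError",
    "read_record",
    "write_record",
    "normalize_record",
    "denormalize_channel",
    "read_annotation",
    "write_annotation",
]

#: fixed channel order used throughout the pipeline
CHANNELS = ("ppg", "acc_x", "acc_y", "acc_z")

DEFAULT_SAMPLING_RATE = 32.0


class FormatError(ValueError):
    """Raised when an on-disk record violates the documented CSV dialect."""


@dataclass
class SignalRecord:
    """Uniformly sampled multichannel record (PPG + 3-axis acceleration).

    Parameters
    ----------
    ppg, acc_x, acc_y, acc_z
        Equal-length real-valued channels.
    target
        Optional idealised reference PPG (same length).
    sampling_rate
        Samples per second, > 0.
    record_id
        Free-form identifier used in dataset provenance.
    norm_params
        Per-channel ``(offset, scale)`` of the affine normalization
        ``x_norm = (x - offset) / scale``; ``scale == 0`` marks a
        constant channel mapped to zeros.
    """

    ppg: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    target: np.ndarray | None = None
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    record_id: str = ""
    norm_params: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in CHANNELS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.target is not None:
            self.target = np.asarray(self.target, dtype=float)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n = len(self.ppg)
        if n < 2:
            raise ValueError("record channels must have length >= 2")
        for name in CHANNELS:
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length differs from ppg")
        if self.target is not None and len(self.target) != n:
            raise ValueError("target length differs from channels")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    # -- conveniences ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.ppg)

    @property
    def duration(self) -> float:
        """Record duration in seconds (n samples at fixed rate)."""
        return len(self) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, 0-based index / sampling_rate."""
        return np.arange(len(self)) / self.sampling_rate

    def channels(self) -> dict[str, np.ndarray]:
        out = {name: getattr(self, name) for name in CHANNELS}
        if self.target is not None:
            out["target"] = self.target
        return out

    def replace(self, **kwargs) -> "SignalRecord":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PeakAnnotation:
    """Ordered peak times with optional clean-window boundaries.

    ``window_a_end`` closes the movement-free head window (Time Window A)
    and ``window_b_start`` opens the movement-free tail window (Time
    Window B).  Detector output leaves both unset.
    """

    peak_times: np.ndarray
    window_a_end: float | None = None
    window_b_start: float | None = None

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.validate()

    def validate(self) -> None:
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")
        if (self.window_a_end is None) != (self.window_b_start is None):
            raise ValueError("window boundaries must be set together")
        if self.window_a_end is not None:
            if not self.window_a_end < self.window_b_start:
                raise ValueError("window_a_end must precede window_b_start")

    def peaks_before(self, t: float) -> np.ndarray:
        return self.peak_times[self.peak_times <= t]

    def peaks_after(self, t: float) -> np.ndarray:
        return self.peak_times[self.peak_times >= t]

    def __len__(self) -> int:
        return len(self.peak_times)


# ---------------------------------------------------------------------------
# record CSV I/O — dialect: header t,ppg,acc_x,acc_y,acc_z[,target]
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("t",) + CHANNELS


def read_record(path: str | Path, dialect: str = "csv") -> SignalRecord:
    """Read a record from the documented CSV dialect.

    The file must carry the header ``t,ppg,acc_x,acc_y,acc_z`` with an
    optional trailing ``target`` column; ``t`` is seconds, ascending at a
    fixed step that determines the sampling rate.
    """
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} in header")
    if df.isna().any().any():
        line = int(df.isna().any(axis=1).idxmax()) + 2  # +2: header + 1-based
        raise FormatError(f"{path}: ragged/missing value at line {line}")
    t = df["t"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(t) < 2 or np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 3 if len(t) >= 2 else 2
        raise FormatError(f"{path}: time column not strictly increasing at line {bad}")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > 1e-6 * max(step, 1.0):
        bad = int(np.argmax(np.abs(dt - step) > 1e-6 * max(step, 1.0))) + 3
        raise FormatError(f"{path}: non-uniform time step at line {bad}")
    target = df["target"].to_numpy(dtype=float) if "target" in df.columns else None
    return SignalRecord(
        ppg=df["ppg"].to_numpy(dtype=float),
        acc_x=df["acc_x"].to_numpy(dtype=float),
        acc_y=df["acc_y"].to_numpy(dtype=float),
        acc_z=df["acc_z"].to_numpy(dtype=float),
        target=target,
        sampling_rate=1.0 / step,
        record_id=path.stem,
    )


def write_record(record: SignalRecord, path: str | Path) -> None:
    """Write a record in the CSV dialect; round-trips to < 1e-9 per channel."""
    record.validate()
    path = Path(path)
    cols = {"t": record.times}
    cols.update(record.channels())
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# annotation I/O — peak CSV + sidecar YAML with window boundaries
# ---------------------------------------------------------------------------

def write_annotation(annotation: PeakAnnotation, path: str | Path) -> None:
    """Write peaks to ``path`` (CSV, column ``peak_time``) and the window
    boundaries to a ``.windows.yaml`` sidecar next to it."""
    path = Path(path)
    pd.DataFrame({"peak_time": annotation.peak_times}).to_csv(
        path, index=False, float_format="%.17g"
    )
    if annotation.window_a_end is not None:
        sidecar = path.with_suffix(".windows.yaml")
        sidecar.write_text(
            yaml.safe_dump(
                {
                    "window_a_end": float(annotation.window_a_end),
                    "window_b_start": float(annotation.window_b_start),
                }
            )
        )


def read_annotation(path: str | Path) -> PeakAnnotation:
    path = Path(path)
    df = pd.read_csv(path)
    if "peak_time" not in df.columns:
        raise FormatError(f"{path}: missing 'peak_time' column")
    window_a_end = window_b_start = None
    sidecar = path.with_suffix(".windows.yaml")
    if sidecar.exists():
        cfg = yaml.safe_load(sidecar.read_text())
        window_a_end = cfg["window_a_end"]
        window_b_start = cfg["window_b_start"]
    return PeakAnnotation(
        peak_times=df["peak_time"].to_numpy(dtype=float),
        window_a_end=window_a_end,
        window_b_start=window_b_start,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _minmax(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    offset = 0.5 * (hi + lo)
    scale = 0.5 * (hi - lo)
    if scale == 0.0:
        return np.zeros_like(x), offset, 0.0
    return (x - offset) / scale, offset, scale


def normalize_record(record: SignalRecord) -> SignalRecord:
    """Per-channel min-max normalization onto [-1, 1].

    Channel minimum maps to -1 and maximum to +1; the affine parameters
    are stored in ``norm_params`` so the mapping is invertible.  A
    constant channel maps to all-zeros with scale recorded as 0.
    """
    out: dict[str, np.ndarray] = {}
    params: dict[str, tuple[float, float]] = {}
    names = list(CHANNELS) + (["target"] if record.target is not None else [])
    for name in names:
        normed, offset, scale = _minmax(getattr(record, name))
        out[name] = normed
        params[name] = (offset, scale)
    return record.replace(norm_params=params, **out)


def denormalize_channel(record: SignalRecord, name: str) -> np.ndarray:
    """Invert the stored normalization of one channel."""
    offset, scale = record.norm_params[name]
    x = getattr(record, name)
    if scale == 0.0:
        return np.full_like(x, offset)
    return x * scale + offset
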