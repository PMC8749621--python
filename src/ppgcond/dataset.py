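"""Segmentation of normalized records into fixed-length training sequences.

A sequence of length ``L`` with inter-sampling stride ``S`` ending at
sample ``e`` takes the samples ``e-(L-1)S, e-(L-2)S, ..., e`` from each
of the four input channels (feature order: ppg, acc_x, acc_y, acc_z) and
is paired with the target value at ``e`` — the causal choice that a
real-time conditioner needs.  Consecutive sequences advance by ``hop``
samples (1 by default, which is also what continuous inference uses).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .signal_core import CHANNELS, SignalRecord

__all__ = [
    "SequenceDataset",
    "segment_record",
    "merge_datasets",
    "split_train_eval",
    "save_dataset",
    "load_dataset",
    "span",
]

FEATURE_ORDER = CHANNELS  # (ppg, acc_x, acc_y, acc_z); must match at inference


def span(L: int, S: int) -> int:
    """Number of raw samples one sequence reaches back over: (L-1)*S + 1."""
    return (L - 1) * S + 1


@dataclass
class SequenceDataset:
    """3-D training array with per-sequence scalar targets.

    sequences: (num_sequences, L, 4) in feature order ppg, acc_x, acc_y,
    acc_z; targets: (num_sequences,); provenance: (record_id, end-sample
    index) per sequence.
    """

    sequences: np.ndarray
    targets: np.ndarray
    L: int
    S: int
    hop: int
    provenance: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        n = len(self.targets)
        if self.sequences.shape != (n, self.L, len(FEATURE_ORDER)):
            raise ValueError("sequence array shape inconsistent with targets/L")
        if len(self.provenance) != n:
            raise ValueError("provenance length mismatch")

    def __len__(self) -> int:
        return len(self.targets)


def segment_record(
    record: SignalRecord, L: int, S: int, hop: int = 1
) -> SequenceDataset:
    """Cut one normalized, targeted record into training sequences.

    End indices run from ``(L-1)*S`` to ``len(record)-1`` stepped by
    ``hop``; a record shorter than one span yields an empty dataset with
    a warning.
    """
    if record.target is None:
        raise ValueError("record has no target channel")
    if L < 1 or S < 1 or hop < 1:
        raise ValueError("L, S and hop must be >= 1")
    n = len(record)
    first_end = (L - 1) * S
    if first_end > n - 1:
        warnings.warn(
            f"record {record.record_id!r} shorter than one span "
            f"({span(L, S)} samples); empty dataset"
        )
        return SequenceDataset(
            np.empty((0, L, len(FEATURE_ORDER))), np.empty(0), L, S, hop, []
        )
    ends = np.arange(first_end, n, hop)
    # sample indices per sequence: ends[:, None] - (L-1-j)*S
    idx = ends[:, None] - S * np.arange(L - 1, -1, -1)[None, :]
    features = np.stack([getattr(record, c) for c in FEATURE_ORDER], axis=-1)
    sequences = features[idx]  # (num, L, 4)
    targets = record.target[ends]
    provenance = [(record.record_id, int(e)) for e in ends]
    return SequenceDataset(sequences, targets, L, S, hop, provenance)


def merge_datasets(parts: list[SequenceDataset]) -> SequenceDataset:
    """Concatenate datasets sharing L and S, preserving provenance."""
    if not parts:
        raise ValueError("nothing to merge")
    first = parts[0]
    for p in parts[1:]:
        if p.L != first.L or p.S != first.S:
            raise ValueError("cannot merge datasets with differing L or S")
    return SequenceDataset(
        np.concatenate([p.sequences for p in parts]),
        np.concatenate([p.targets for p in parts]),
        first.L,
        first.S,
        first.hop,
        [pr for p in parts for pr in p.provenance],
    )


def split_train_eval(records: list, n_train: int, seed: int) -> tuple[list, list]:
    """Deterministic record-level shuffled split (never sequence-level,
    which would leak overlapping windows between train and eval)."""
    if n_train >= len(records):
        raise ValueError("n_train must be smaller than the number of records")
    order = np.random.default_rng(seed).permutation(len(records))
    train = [records[i] for i in order[:n_train]]
    evaluation = [records[i] for i in order[n_train:]]
    return train, evaluation


# ---------------------------------------------------------------------------
# single-file container (.npz with JSON metadata)
# ---------------------------------------------------------------------------

def save_dataset(dataset: SequenceDataset, path: str | Path) -> None:
    meta = {
        "L": dataset.L,
        "S": dataset.S,
        "hop": dataset.hop,
        "feature_order": list(FEATURE_ORDER),
        "provenance": [[rid, e] for rid, e in dataset.provenance],
    }
    np.savez(
        path,
        sequences=dataset.sequences,
        targets=dataset.targets,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_dataset(path: str | Path) -> SequenceDataset:
    with np.load(path) as data:
        meta = json.loads(data["meta"].tobytes().decode())
        return SequenceDataset(
            data["sequences"],
            data["targets"],
            meta["L"],
            meta["S"],
            meta["hop"],
            [(rid, int(e)) for rid, e in meta["provenance"]],
        )
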