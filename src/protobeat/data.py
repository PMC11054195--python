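"""Core containers for labeled single-beat time series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LabeledSequence:
    """One fixed-length univariate time series (e.g. a single heartbeat) with a class label.

    Attributes
    ----------
    values : ndarray of shape (L,)
        Raw signal samples, arbitrary units (millivolts for ECG).
    label : int
        Class index in ``{0, ..., C-1}``.
    id : str
        Opaque identifier, unique within a dataset.
    """

    values: np.ndarray
    label: int
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("sequence values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sequence contains non-finite samples")
        if self.label < 0:
            raise ValueError(f"label must be a non-negative class index, got {self.label}")

    def __len__(self) -> int:
        return self.values.size


def sequences_to_arrays(seqs: list[LabeledSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Stack equal-length sequences into an ``(N, L)`` matrix and an ``(N,)`` label vector."""
    if not seqs:
        raise ValueError("empty sequence list")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    X = np.stack([s.values for s in seqs])
    y = np.array([s.label for s in seqs], dtype=np.int64)
    return X, y


def arrays_to_sequences(
    X: np.ndarray, y: np.ndarray, ids: list[str] | None = None
) -> list[LabeledSequence]:
    """Inverse of :func:`sequences_to_arrays`."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (N, L) with one label per row")
    if ids is None:
        ids = [f"seq{i}" for i in range(X.shape[0])]
    return [LabeledSequence(X[i], int(y[i]), ids[i]) for i in range(X.shape[0])]
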